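"""Synthetic maternity-colony telemetry generator.

Emulates the data structure produced by radio-tracking a fission-fusion bat
maternity colony over one summer season: daily diurnal roost relocations for
a set of tagged bats, nightly foraging fixes, and dusk emergence (exit)
counts at roosts.  The statistical structure targeted is the one the
downstream analyses assume: roost choice concentrated on one shared
"primary" roost plus many lightly used secondary roosts, roost switching
every few days, and serially autocorrelated foraging movement around a
bat-specific foraging centre.

Nothing here is intended as a mechanistic movement model; the generator
exists so every downstream stage (network construction, null tests, UD
estimation, removal simulations) is testable without field data.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ColonyConfig",
    "Colony",
    "roost_preference_matrix",
    "generate_colony",
    "write_colony_csvs",
    "read_colony_csvs",
]

# Named substreams: each stage of the generator draws from its own child of
# the global seed so that toggling one stage never perturbs another.
_STAGES = (
    "layout",       # roost coordinates, bat attributes, tracking windows
    "preferences",  # per-bat roost preference vectors
    "roosting",     # daily roost choices
    "foraging",     # nightly fix sequences
    "exit_counts",  # emergence count sampling
)


@dataclass(frozen=True)
class ColonyConfig:
    """Parameters of one synthetic colony-year.

    Defaults reproduce the tracking-effort scale of a mid-western maternity
    colony study season: ~21 tagged bats, 33 candidate roosts, a mean of
    ~9 tracked days per bat, roost switching roughly every 3.3 days, and
    nightly foraging sequences dense enough that well-tracked bats
    accumulate 40-70+ fixes.
    """

    n_tagged_bats: int = 21
    n_untagged_bats: int = 60
    n_roosts: int = 33
    #: Zipf exponent of the shared colony-level roost-weight backbone.
    #: 0 = exchangeable roosts; large values concentrate all use on the
    #: primary roost.  ``inf`` is the degenerate point-mass case.
    primary_concentration: float = 1.0
    #: Dirichlet concentration of per-bat perturbations around the backbone.
    #: Small values give bats idiosyncratic secondary roosts.
    preference_strength: float = 6.0
    daily_switch_prob: float = 0.30
    #: truncated-normal spec for tracked days per bat
    tracking_days_per_bat: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 9.3, "sd": 5.0, "min": 3, "max": 25}
    )
    season_days: int = 90
    season_start: str = "2009-06-01"
    fixes_per_night: int = 8
    night_duration_min: float = 360.0
    #: number of shared foraging patches (hotspots) bats are assigned to
    n_foraging_patches: int = 2
    #: spread (m) of patch centres around the colony centre
    foraging_center_spread_m: float = 1500.0
    #: jitter (m) of a bat's own centre around its patch centre
    foraging_patch_jitter_m: float = 75.0
    movement_step_sd_m: float = 390.0
    #: mean reversion toward the foraging centre per step, in (0, 1]
    movement_attraction: float = 0.5
    #: spatial scatter (m) of roosts around the colony centre
    roost_spread_m: float = 1200.0
    #: probability that any given roost-night receives an exit count
    exit_count_prob: float = 0.15
    seed: int = 0
    #: seed of the persistent landscape (foraging patch locations); shared
    #: across colony-years by default so foraging areas are stable
    #: between years while roost use is not
    landscape_seed: int = 777

    def validate(self) -> None:
        if min(self.n_tagged_bats, self.n_roosts, self.fixes_per_night) < 1:
            raise ValueError("counts must be positive")
        if self.n_untagged_bats < 0:
            raise ValueError("n_untagged_bats must be >= 0")
        if not (0.0 < self.daily_switch_prob <= 1.0):
            raise ValueError("daily_switch_prob must be in (0, 1]")
        if np.isnan(self.primary_concentration) or self.primary_concentration < 0:
            raise ValueError("primary_concentration must be a non-negative scalar")
        if not np.isfinite(self.preference_strength) or self.preference_strength <= 0:
            raise ValueError("preference_strength must be positive and finite")
        if self.night_duration_min < 3.0 * self.fixes_per_night:
            raise ValueError("night too short for >=3 min fix spacing")


@dataclass
class Colony:
    """Tables of one synthetic colony-year (tidy pandas frames)."""

    relocations: pd.DataFrame  # bat_id, date, roost_id
    fixes: pd.DataFrame        # bat_id, timestamp, x_m, y_m
    exit_counts: pd.DataFrame  # roost_id, date, count
    bats: pd.DataFrame         # bat_id, age_class, sex, repro
    roosts: pd.DataFrame       # roost_id, x_m, y_m
    config: ColonyConfig | None = None


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _backbone(config: ColonyConfig) -> np.ndarray:
    """Colony-level roost weights: Zipf over roost rank."""
    ranks = np.arange(1, config.n_roosts + 1, dtype=float)
    if np.isinf(config.primary_concentration):
        w = np.zeros(config.n_roosts)
        w[0] = 1.0
        return w
    w = ranks ** (-config.primary_concentration)
    return w / w.sum()


def roost_preference_matrix(
    config: ColonyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-bat roost-choice probability vectors, shape (n_bats, n_roosts).

    Each bat's vector is a Dirichlet perturbation of the shared Zipf
    backbone: ``Dirichlet(strength * n_roosts * backbone)``.  At
    ``primary_concentration = 0`` the backbone is uniform and the vectors
    are exchangeable across roosts; as it grows the shared primary roost
    absorbs all mass; at ``inf`` every vector is exactly a point mass on
    roost 1.
    """
    config.validate()
    m = _backbone(config)
    if np.isinf(config.primary_concentration):
        return np.tile(m, (config.n_tagged_bats, 1))
    alpha = config.preference_strength * config.n_roosts * m
    # Dirichlet via gamma draws; alpha_j == 0 yields an exact zero component.
    g = rng.gamma(shape=np.tile(alpha, (config.n_tagged_bats, 1)), scale=1.0)
    g = np.where(np.tile(alpha, (config.n_tagged_bats, 1)) > 0, np.maximum(g, 1e-300), 0.0)
    return g / g.sum(axis=1, keepdims=True)


def _tracking_lengths(config: ColonyConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.tracking_days_per_bat
    lo, hi = float(spec.get("min", 1)), float(spec.get("max", config.season_days))
    draws = rng.normal(spec["mean"], spec["sd"], size=config.n_tagged_bats)
    return np.clip(np.rint(draws), lo, hi).astype(int)


def _bat_attributes(config: ColonyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Adult-female-dominated composition with a juvenile minority."""
    n = config.n_tagged_bats
    adult = rng.random(n) < 2.0 / 3.0
    age = np.where(adult, "adult", "juvenile")
    # adults in a maternity colony are female; juveniles of either sex
    sex = np.where(adult, "F", np.where(rng.random(n) < 0.5, "F", "M"))
    repro_levels = np.array(["pregnant", "lactating", "post-lactating", "unknown"])
    repro = np.where(
        adult, repro_levels[rng.integers(0, 4, size=n)], "non-reproductive"
    )
    return pd.DataFrame(
        {
            "bat_id": [f"B{i + 1:02d}" for i in range(n)],
            "age_class": age,
            "sex": sex,
            "repro": repro,
        }
    )


def generate_colony(config: ColonyConfig) -> Colony:
    """Simulate one colony-year of relocations, fixes and exit counts.

    Roosting: each bat has a contiguous tracking window; on its first day it
    draws a roost from its preference vector, and on each later day it stays
    put with probability ``1 - daily_switch_prob``, otherwise redraws from
    the preference vector (a redraw may land on the same roost).

    Foraging: each tracked night yields ``fixes_per_night`` fixes from a
    discrete correlated random walk attracted to a bat-specific centre,
    with strictly increasing timestamps spaced >= 3 minutes apart.

    Exit counts: sampled roost-nights report tagged occupants plus untagged
    colony members, the latter distributed over roosts by the colony
    backbone; sampled nights with zero occupants report zero.
    """
    config.validate()
    rngs = _stage_rngs(config.seed)
    season_start = _dt.date.fromisoformat(config.season_start)

    lay = rngs["layout"]
    bats = _bat_attributes(config, lay)
    roost_ids = [f"R{j + 1:02d}" for j in range(config.n_roosts)]
    roost_xy = lay.normal(0.0, config.roost_spread_m, size=(config.n_roosts, 2))
    roost_xy[0] = lay.normal(0.0, config.roost_spread_m / 6.0, size=2)  # primary central
    roosts = pd.DataFrame(
        {"roost_id": roost_ids, "x_m": roost_xy[:, 0], "y_m": roost_xy[:, 1]}
    )
    lengths = _tracking_lengths(config, lay)
    starts = lay.integers(0, np.maximum(1, config.season_days - lengths), endpoint=False)

    prefs = roost_preference_matrix(config, rngs["preferences"])

    ro = rngs["roosting"]
    reloc_rows: list[tuple[str, _dt.date, str]] = []
    occupancy: dict[tuple[str, _dt.date], list[str]] = {}
    if int(lengths.sum()) == 0:
        warnings.warn("zero tracking days: empty colony tables", stacklevel=2)
    for i, bat in enumerate(bats["bat_id"]):
        current = int(ro.choice(config.n_roosts, p=prefs[i]))
        for d in range(lengths[i]):
            if d > 0 and ro.random() < config.daily_switch_prob:
                current = int(ro.choice(config.n_roosts, p=prefs[i]))
            date = season_start + _dt.timedelta(days=int(starts[i]) + d)
            reloc_rows.append((bat, date, roost_ids[current]))
            occupancy.setdefault((roost_ids[current], date), []).append(bat)
    relocations = pd.DataFrame(reloc_rows, columns=["bat_id", "date", "roost_id"])

    fo = rngs["foraging"]
    # bats share a few foraging hotspots: patch centres plus per-bat jitter;
    # patches belong to the landscape and persist across colony-years
    land = np.random.default_rng(np.random.SeedSequence(config.landscape_seed))
    patch_xy = land.normal(
        0.0, config.foraging_center_spread_m, size=(max(config.n_foraging_patches, 1), 2)
    )
    patch_of = fo.integers(0, max(config.n_foraging_patches, 1), size=config.n_tagged_bats)
    centers = patch_xy[patch_of] + fo.normal(
        0.0, config.foraging_patch_jitter_m, size=(config.n_tagged_bats, 2)
    )
    fix_rows = []
    spacing = config.night_duration_min / config.fixes_per_night
    for i, bat in enumerate(bats["bat_id"]):
        pos = centers[i] + fo.normal(0.0, config.movement_step_sd_m, size=2)
        for d in range(lengths[i]):
            date = season_start + _dt.timedelta(days=int(starts[i]) + d)
            night_start = _dt.datetime.combine(date, _dt.time(21, 30))
            t = 0.0
            for k in range(config.fixes_per_night):
                pos = (
                    pos
                    + config.movement_attraction * (centers[i] - pos)
                    + fo.normal(0.0, config.movement_step_sd_m, size=2)
                )
                # whole-minute jitter bounded so consecutive fixes stay
                # strictly increasing and >= 3 minutes apart
                jitter = int(fo.integers(0, max(int(spacing) - 3, 1)))
                t = k * spacing + jitter
                ts = night_start + _dt.timedelta(minutes=round(t))
                fix_rows.append((bat, ts, pos[0], pos[1]))
    fixes = pd.DataFrame(fix_rows, columns=["bat_id", "timestamp", "x_m", "y_m"])
    if not fixes.empty:
        fixes = fixes.sort_values(["bat_id", "timestamp"], kind="stable").reset_index(
            drop=True
        )

    ec = rngs["exit_counts"]
    backbone = _backbone(config)
    exit_rows = []
    all_dates = [
        season_start + _dt.timedelta(days=d) for d in range(config.season_days)
    ]
    for date in all_dates:
        if config.n_untagged_bats > 0:
            untagged = ec.multinomial(config.n_untagged_bats, backbone)
        else:
            untagged = np.zeros(config.n_roosts, dtype=int)
        for j, roost in enumerate(roost_ids):
            if ec.random() >= config.exit_count_prob:
                continue
            tagged = len(occupancy.get((roost, date), ()))
            exit_rows.append((roost, date, int(tagged + untagged[j])))
    exit_counts = pd.DataFrame(exit_rows, columns=["roost_id", "date", "count"])

    return Colony(relocations, fixes, exit_counts, bats, roosts, config)


def write_colony_csvs(colony: Colony, outdir) -> None:
    """Write the five tidy tables as ISO-dated CSVs under *outdir*."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    colony.relocations.to_csv(out / "relocations.csv", index=False)
    f = colony.fixes.copy()
    if not f.empty:
        f["timestamp"] = pd.to_datetime(f["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    f.rename(columns={"timestamp": "timestamp_iso"}).to_csv(
        out / "fixes.csv", index=False
    )
    colony.exit_counts.to_csv(out / "exit_counts.csv", index=False)
    colony.bats.to_csv(out / "bats.csv", index=False)
    colony.roosts.to_csv(out / "roosts.csv", index=False)


def read_colony_csvs(indir) -> Colony:
    from pathlib import Path

    ind = Path(indir)
    relocations = pd.read_csv(ind / "relocations.csv", parse_dates=["date"])
    relocations["date"] = relocations["date"].dt.date
    fixes = pd.read_csv(ind / "fixes.csv")
    fixes = fixes.rename(columns={"timestamp_iso": "timestamp"})
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    exit_counts = pd.read_csv(ind / "exit_counts.csv", parse_dates=["date"])
    exit_counts["date"] = exit_counts["date"].dt.date
    bats = pd.read_csv(ind / "bats.csv")
    roosts = pd.read_csv(ind / "roosts.csv")
    return Colony(relocations, fixes, exit_counts, bats, roosts)
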