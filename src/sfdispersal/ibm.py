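"""Stochastic lattice individual-based model of *S. frugiperda* dynamics.

A rectangular lattice of cotton cells (each Bt or non-Bt) carries two
populations: immatures (0/1 occupancy per cell) and adult females (0–K per
cell, K = 10).  Per time step, demographic transitions (immature mortality,
metamorphosis, adult mortality, oviposition) are followed by larval
dispersal — one uniform draw inside a crop-dependent Chebyshev ball, radius
3 on Bt cells and 1 on non-Bt cells, reflecting the threefold distance
contrast measured for Cry1F-resistant neonates — and adult dispersal within
a Chebyshev radius of 35, respecting the carrying capacity.

Six landscape scenarios (a1–a3: Bt-dominant with 0/10/20% non-Bt
contamination; b1–b3: the non-Bt mirror) are run for 300 steps x 50
replicates; the endpoints are the mean distance of larvae to the centroid
of the larval distribution and the larval density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .util import as_rng, spawn_seeds

BT = "BT"
NONBT = "NONBT"
_CROP_CODE = {NONBT: 0, BT: 1}

SCENARIO_IDS = ("a1", "a2", "a3", "b1", "b2", "b3")

RESULT_COLUMNS = ["scenario", "replicate", "seed", "mean_distance",
                  "larval_density", "final_larvae", "final_adults"]


@dataclass(frozen=True)
class Landscape:
    """Immutable crop map: 1 = Bt cell, 0 = non-Bt cell."""

    crop: np.ndarray            # int8, shape (height, width)
    dominant: str
    contamination: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.crop.shape

    def crop_at(self, cell: tuple[int, int]) -> str:
        return BT if self.crop[cell] == 1 else NONBT

    @property
    def n_contaminated(self) -> int:
        dom = _CROP_CODE[self.dominant]
        return int((self.crop != dom).sum())


def build_landscape(width: int, height: int, dominant: str, fraction: float,
                    rng: np.random.Generator | int | None = None) -> Landscape:
    """Homogeneous ``dominant``-crop field with ``round(fraction*W*H)``
    cells of the other crop placed uniformly at random without replacement.

    Rounding is half-away-from-zero; ``fraction`` must lie in [0, 0.5] so
    the dominant crop stays dominant.
    """
    if dominant not in _CROP_CODE:
        raise ValueError(f"dominant must be one of {sorted(_CROP_CODE)}")
    if not (0.0 <= fraction <= 0.5):
        raise ValueError("contamination fraction must be in [0, 0.5]")
    if width < 1 or height < 1:
        raise ValueError("lattice dimensions must be >= 1")
    rng = as_rng(rng)
    n_cells = width * height
    n_cont = int(np.floor(fraction * n_cells + 0.5))
    dom = _CROP_CODE[dominant]
    crop = np.full((height, width), dom, dtype=np.int8)
    if n_cont:
        flat = rng.choice(n_cells, size=n_cont, replace=False)
        crop.flat[flat] = 1 - dom
    crop.setflags(write=False)
    return Landscape(crop, dominant, fraction)


@dataclass(frozen=True)
class TransitionRates:
    """Per-step event probabilities.

    The published model's probability functions are not available in the
    main text; these defaults are this package's own calibration, chosen so
    that a population seeded in the lattice centre persists over 300 steps
    without saturating the lattice, and so that the simulated endpoints
    reproduce the reported qualitative contrast (larval spread driven by
    the crop-dependent movement radius, insensitive to 10-20%
    contamination).  See docs/methods.md for the calibration rationale.
    """

    immature_mortality: float = 0.006
    metamorphosis: float = 0.008
    adult_mortality: float = 0.10
    oviposition: float = 0.25

    def __post_init__(self) -> None:
        for name in ("immature_mortality", "metamorphosis",
                     "adult_mortality", "oviposition"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation condition: landscape spec plus all rates and radii."""

    scenario: str = "a1"
    dominant: str = BT
    contamination: float = 0.0
    width: int = 100
    height: int = 100
    r_bt: int = 3
    r_nonbt: int = 1
    adult_radius: int = 35
    carrying_capacity: int = 10
    steps: int = 300
    replicates: int = 50
    rates: TransitionRates = field(default_factory=TransitionRates)
    init_block: int = 14       # side of the centred, fully occupied larval block
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.r_bt, self.r_nonbt, self.adult_radius) < 0:
            raise ValueError("radii must be >= 0")
        if self.steps < 0 or self.replicates < 1:
            raise ValueError("steps must be >= 0 and replicates >= 1")

    def radii(self) -> dict[str, int]:
        return {BT: self.r_bt, NONBT: self.r_nonbt}


#: Scenario battery: a1–a3 Bt-dominant, b1–b3 non-Bt-dominant, with
#: 0 / 10 / 20 % contamination by the opposite crop.
_BATTERY_SPEC = {
    "a1": (BT, 0.0), "a2": (BT, 0.10), "a3": (BT, 0.20),
    "b1": (NONBT, 0.0), "b2": (NONBT, 0.10), "b3": (NONBT, 0.20),
}


def default_battery(master_seed: int = 0, **overrides) -> dict[str, ScenarioConfig]:
    """The six default scenario configurations, sharing rates and sizes."""
    seeds = spawn_seeds(master_seed, len(SCENARIO_IDS))
    return {
        sid: ScenarioConfig(scenario=sid, dominant=dom, contamination=frac,
                            seed=seeds[i], **overrides)
        for i, (sid, (dom, frac)) in enumerate(_BATTERY_SPEC.items())
    }


# ---------------------------------------------------------------------------
# Elementary operations (thin wrappers over the compiled kernels)
# ---------------------------------------------------------------------------

def dispersal_neighbourhood(cell: tuple[int, int], landscape: Landscape,
                            radii: dict[str, int]) -> list[tuple[int, int]]:
    """Candidate destination cells for a larva at ``cell``: the Chebyshev
    ball of the radius assigned to the cell's crop, clipped at the lattice
    edges, excluding the origin."""
    H, W = landscape.shape
    r, c = cell
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"cell {cell} outside the {H}x{W} lattice")
    R = radii[landscape.crop_at(cell)]
    return [(i, j)
            for i in range(max(0, r - R), min(H - 1, r + R) + 1)
            for j in range(max(0, c - R), min(W - 1, c + R) + 1)
            if (i, j) != (r, c)]


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2 ** 31 - 1))


def larval_dispersal_step(larvae: np.ndarray, landscape: Landscape,
                          radii: dict[str, int],
                          rng: np.random.Generator) -> np.ndarray:
    """One synchronous-population larval dispersal step (returns a new grid).

    Larvae are processed in random order; each draws one uniform candidate
    in its neighbourhood and moves iff that cell is currently empty.
    """
    out = np.ascontiguousarray(larvae, dtype=np.int8).copy()
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    _kernels.larval_step(out, landscape.crop, radii[BT], radii[NONBT])
    return out


def adult_dispersal_step(adults: np.ndarray, rng: np.random.Generator,
                         radius: int = 35, carrying_capacity: int = 10
                         ) -> np.ndarray:
    """One adult dispersal step: per female, one uniform candidate within
    ``radius``; the move happens iff the destination is below capacity."""
    out = np.ascontiguousarray(adults, dtype=np.int16).copy()
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    _kernels.adult_step(out, radius, carrying_capacity)
    return out


def transition_step(larvae: np.ndarray, adults: np.ndarray,
                    rates: TransitionRates, rng: np.random.Generator,
                    carrying_capacity: int = 10
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Demographic events for one step (returns new grids)."""
    L = np.ascontiguousarray(larvae, dtype=np.int8).copy()
    A = np.ascontiguousarray(adults, dtype=np.int16).copy()
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    _kernels.transition(L, A, rates.immature_mortality, rates.metamorphosis,
                        rates.adult_mortality, rates.oviposition,
                        carrying_capacity)
    return L, A


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------

def mean_distance_to_centre(larvae: np.ndarray) -> float:
    """Mean Euclidean distance of occupied cells to the centroid of the
    occupied cells (the centre of the larval distribution)."""
    coords = np.argwhere(np.asarray(larvae) == 1)
    if coords.shape[0] == 0:
        raise ValueError("no larvae on the grid")
    centroid = coords.mean(axis=0)
    return float(np.linalg.norm(coords - centroid, axis=1).mean())


def larval_density(larvae: np.ndarray) -> float:
    """Occupied cells divided by total cells."""
    L = np.asarray(larvae)
    return float(L.sum() / L.size)


# ---------------------------------------------------------------------------
# Replicates and batteries
# ---------------------------------------------------------------------------

def initial_grids(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fully occupied central ``init_block`` x ``init_block`` larval square,
    no initial adults."""
    L = np.zeros((config.height, config.width), dtype=np.int8)
    b = min(config.init_block, config.height, config.width)
    r0 = (config.height - b) // 2
    c0 = (config.width - b) // 2
    L[r0:r0 + b, c0:c0 + b] = 1
    A = np.zeros((config.height, config.width), dtype=np.int16)
    return L, A


def run_replicate(config: ScenarioConfig, replicate_seed: int,
                  replicate: int = 0) -> dict:
    """One full simulation run; returns one result row as a dict.

    On extinction before the final step the distance endpoint is missing
    (NaN) and density is 0.
    """
    rng = as_rng(replicate_seed)
    landscape = build_landscape(config.width, config.height, config.dominant,
                                config.contamination, rng)
    L, A = initial_grids(config)
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    _kernels.run_steps(L, A, landscape.crop, config.r_bt, config.r_nonbt,
                       config.adult_radius, config.carrying_capacity,
                       config.rates.immature_mortality,
                       config.rates.metamorphosis,
                       config.rates.adult_mortality,
                       config.rates.oviposition,
                       config.steps)
    n_larvae = int(L.sum())
    return {
        "scenario": config.scenario,
        "replicate": replicate,
        "seed": replicate_seed,
        "mean_distance": mean_distance_to_centre(L) if n_larvae else np.nan,
        "larval_density": larval_density(L),
        "final_larvae": n_larvae,
        "final_adults": int(A.sum()),
    }


def run_scenario(config: ScenarioConfig) -> pd.DataFrame:
    """All replicates of one scenario, with per-replicate child seeds."""
    seeds = spawn_seeds(config.seed, config.replicates)
    rows = [run_replicate(config, s, i) for i, s in enumerate(seeds)]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_battery(configs: dict[str, ScenarioConfig] | None = None,
                master_seed: int = 0, **overrides
                ) -> tuple[pd.DataFrame, dict[str, "pd.DataFrame"]]:
    """Run the six-scenario battery and compare scenarios pairwise.

    Returns the stacked replicate table and, per endpoint, the
    Tukey–Kramer pairwise table with compact letters (as produced by
    :func:`sfdispersal.stats.tukey_pairwise`).
    """
    from .stats import tukey_pairwise  # local import to avoid a cycle

    if configs is None:
        configs = default_battery(master_seed, **overrides)
    results = pd.concat([run_scenario(c) for c in configs.values()],
                        ignore_index=True)
    comparisons = {}
    if len(configs) < 2:
        return results, comparisons
    for endpoint in ("mean_distance", "larval_density"):
        res = tukey_pairwise(results, endpoint, "scenario")
        tab = res.pairs.copy()
        tab["letters_a"] = tab["group_a"].map(res.letters)
        tab["letters_b"] = tab["group_b"].map(res.letters)
        comparisons[endpoint] = tab
    return results, comparisons
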