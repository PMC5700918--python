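"""Synthetic bioassay and video-tracking data generator.

Emulates the two laboratory experiments behind the behavioural analyses:

* a factorial host-acceptance bioassay in which cotton plants (Bt and the
  non-Bt isoline) each receive 20 *Spodoptera frugiperda* neonates and, after
  a fixed exposure interval, every larva is classified by location
  (on / off the plant), feeding status (fed / not fed) and recovery
  (recovered alive / unrecovered);

* a video-tracking assay yielding per-larva movement endpoints (distance
  moved in cm, mean velocity in cm/s, continuous mobility period in s).

Survival over exposure time follows a logistic-in-time model per strain;
location and feeding are conditional Bernoulli probabilities.  All five
larval fates on a plant are drawn as a single multinomial so that the count
identity ``on_fed + on_notfed + off_fed + off_notfed + unrecovered ==
released`` holds exactly on every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .util import expit, as_rng

SS = "SS"
RR = "RR"
BT_WS = "BT_WS"   # WideStrike (Cry1Ac/Cry1F)
BT_TL = "BT_TL"   # TwinLink (Cry1Ab/Cry2Ae)
NONBT = "NONBT"   # untransformed isoline

BIOASSAY_COLUMNS = [
    "block", "strain", "variety", "interval_h", "released",
    "on_fed", "on_notfed", "off_fed", "off_notfed", "unrecovered",
]
TRACK_COLUMNS = ["strain", "variety", "distance_cm", "velocity_cm_s", "mobility_s"]

#: Logistic survival coefficients (intercept, slope per hour) per strain.
#: Susceptible larvae die off quickly on Bt tissue; the Cry1F-resistant
#: strain declines far more slowly.
DEFAULT_SURVIVAL_LOGIT: dict[str, tuple[float, float]] = {
    SS: (2.7690, -0.1470),
    RR: (1.1089, -0.0483),
}

#: Probability that a recovered-alive larva is found on the plant, per
#: strain x exposure interval (hours).  Susceptible larvae abandon the plant
#: over time; resistant larvae become increasingly sedentary on it.
DEFAULT_ON_PLANT_PROB: dict[tuple[str, int], float] = {
    (SS, 6): 0.6483, (SS, 12): 0.5900, (SS, 18): 0.3350, (SS, 24): 0.4798,
    (RR, 6): 0.6268, (RR, 12): 0.6580, (RR, 18): 0.7580, (RR, 24): 0.7338,
}


def _default_fed_probs(strains: Sequence[str], varieties: Sequence[str]
                       ) -> tuple[dict, dict]:
    """Feeding probabilities conditional on location.

    Resistant larvae feed readily on any tissue; susceptible larvae feed
    less on Bt tissue (deterrence/intoxication).  Off-plant larvae are less
    often scored as fed because pre-feeding dispersers never ingested tissue.
    """
    fed_on, fed_off = {}, {}
    for s in strains:
        for v in varieties:
            bt = v != NONBT
            if s == SS and bt:
                fed_on[(s, v)] = 0.55
                fed_off[(s, v)] = 0.35
            else:
                fed_on[(s, v)] = 0.80
                fed_off[(s, v)] = 0.45
    return fed_on, fed_off


@dataclass(frozen=True)
class BioassayDesign:
    """Factorial randomized-block layout of the host-acceptance bioassay."""

    n_blocks: int = 4
    strains: tuple[str, ...] = (SS, RR)
    varieties: tuple[str, ...] = (BT_WS, NONBT)
    intervals_h: tuple[int, ...] = (6, 12, 18, 24)
    larvae_per_plant: int = 20

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.larvae_per_plant < 1:
            raise ValueError("n_blocks and larvae_per_plant must be positive")
        if not self.strains or not self.varieties or not self.intervals_h:
            raise ValueError("design factors must be non-empty")
        for name, labels in (("strains", self.strains),
                             ("varieties", self.varieties),
                             ("intervals_h", self.intervals_h)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} labels must be unique")
        if any(b >= a for a, b in zip(self.intervals_h[1:], self.intervals_h)):
            raise ValueError("intervals_h must be strictly increasing")

    @property
    def n_records(self) -> int:
        return (self.n_blocks * len(self.strains) * len(self.varieties)
                * len(self.intervals_h))


@dataclass
class BioassayParams:
    """Probability model driving the larval-fate multinomial.

    survival_logit
        per-strain ``(intercept, slope)`` of the logistic survival curve in
        exposure time (hours, logit scale).
    on_plant_prob
        P(on plant | recovered alive) per (strain, interval).
    fed_given_on_prob / fed_given_off_prob
        P(fed | location) per (strain, variety).
    """

    survival_logit: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_LOGIT))
    on_plant_prob: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_ON_PLANT_PROB))
    fed_given_on_prob: Mapping[tuple[str, str], float] | None = None
    fed_given_off_prob: Mapping[tuple[str, str], float] | None = None
    seed: int | None = None

    def resolve(self, design: BioassayDesign) -> "BioassayParams":
        """Fill per-cell probability tables for every design cell, validating."""
        fed_on, fed_off = _default_fed_probs(design.strains, design.varieties)
        if self.fed_given_on_prob is not None:
            fed_on = dict(self.fed_given_on_prob)
        if self.fed_given_off_prob is not None:
            fed_off = dict(self.fed_given_off_prob)
        out = BioassayParams(dict(self.survival_logit), dict(self.on_plant_prob),
                             fed_on, fed_off, self.seed)
        for s in design.strains:
            if s not in out.survival_logit:
                raise ValueError(f"no survival model for strain {s!r}")
            for t in design.intervals_h:
                p = out.on_plant_prob.get((s, t))
                if p is None:
                    raise ValueError(f"no on-plant probability for ({s}, {t})")
                _check_prob(p, f"on_plant_prob[{s},{t}]")
            for v in design.varieties:
                for table, name in ((fed_on, "fed_given_on_prob"),
                                    (fed_off, "fed_given_off_prob")):
                    p = table.get((s, v))
                    if p is None:
                        raise ValueError(f"no {name} for ({s}, {v})")
                    _check_prob(p, f"{name}[{s},{v}]")
        return out

    def fate_probabilities(self, strain: str, variety: str, interval_h: int
                           ) -> np.ndarray:
        """Five-category probabilities (on_fed, on_notfed, off_fed,
        off_notfed, unrecovered) for one design cell."""
        b0, b1 = self.survival_logit[strain]
        s = expit(b0 + b1 * interval_h)
        p_on = self.on_plant_prob[(strain, interval_h)]
        p_fo = self.fed_given_on_prob[(strain, variety)]
        p_ff = self.fed_given_off_prob[(strain, variety)]
        p = np.array([
            s * p_on * p_fo,
            s * p_on * (1.0 - p_fo),
            s * (1.0 - p_on) * p_ff,
            s * (1.0 - p_on) * (1.0 - p_ff),
            1.0 - s,
        ])
        # guard against tiny negative rounding
        p = np.clip(p, 0.0, 1.0)
        return p / p.sum()


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} = {p} outside [0, 1]")


def generate_bioassay(design: BioassayDesign, params: BioassayParams,
                      rng: np.random.Generator | int | None = None
                      ) -> pd.DataFrame:
    """Draw one full factorial bioassay table.

    Returns one row per block x strain x variety x interval; each row's five
    fate counts are a single multinomial draw of size ``larvae_per_plant``.
    Identical seeds give identical tables.
    """
    params = params.resolve(design)
    if rng is None:
        rng = params.seed
    rng = as_rng(rng)
    rows = []
    for block in range(1, design.n_blocks + 1):
        for strain in design.strains:
            for variety in design.varieties:
                for t in design.intervals_h:
                    p = params.fate_probabilities(strain, variety, t)
                    counts = rng.multinomial(design.larvae_per_plant, p)
                    rows.append((block, strain, variety, t,
                                 design.larvae_per_plant, *counts))
    return pd.DataFrame(rows, columns=BIOASSAY_COLUMNS)


# ---------------------------------------------------------------------------
# Video-tracking endpoints
# ---------------------------------------------------------------------------

#: Default group mean (distance cm, velocity cm/s, mobility s) per
#: strain x variety for the tracking assay.  The resistant strain on non-Bt
#: cotton moves one third the distance it does on Bt cotton — the fitness
#: cost signature: resistant neonates are sedentary on their suitable host.
DEFAULT_TRACK_MEANS: dict[tuple[str, str], tuple[float, float, float]] = {
    (SS, BT_WS): (14.0, 14.0 / 43200.0, 700.0),
    (SS, NONBT): (11.0, 11.0 / 43200.0, 650.0),
    (RR, BT_WS): (18.0, 18.0 / 43200.0, 900.0),
    (RR, NONBT): (6.0, 6.0 / 43200.0, 300.0),
}


def generate_tracks(n_per_group: int,
                    group_means: Mapping[tuple[str, str],
                                         tuple[float, float, float]] | None = None,
                    dispersion: float = 0.35,
                    rng: np.random.Generator | int | None = None
                    ) -> pd.DataFrame:
    """Draw per-larva movement endpoints with log-normal noise.

    Each endpoint is log-normal with expectation equal to its group mean and
    log-scale standard deviation ``dispersion`` (right-skewed, strictly
    positive — the usual shape of movement-track data).  ``dispersion = 0``
    returns the group means exactly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if group_means is None:
        group_means = DEFAULT_TRACK_MEANS
    for key, means in group_means.items():
        if any(m <= 0 for m in means):
            raise ValueError(f"group means must be positive, got {means} for {key}")
    rng = as_rng(rng)
    rows = []
    sig2 = dispersion ** 2
    for (strain, variety), means in group_means.items():
        mu = np.log(np.asarray(means)) - sig2 / 2.0
        draws = np.exp(rng.normal(mu, dispersion, size=(n_per_group, 3)))
        for d in draws:
            rows.append((strain, variety, *d))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)
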