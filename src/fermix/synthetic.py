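"""Synthetic bench data with known ground truth.

The original study's raw design/response tables, panel sheets and odor
thresholds live in supplementary material that is not machine-readable,
so every pipeline stage is exercised against simulated data whose
generating truth is known exactly:

* mixture responses: a known Scheffe polynomial evaluated on a design,
  plus i.i.d. Gaussian measurement noise per replicate (bench assays
  here are triplicate means with roughly constant SD, so additive
  Gaussian noise on the response scale is the natural model);
* sensory counts: one multinomial draw per attribute from known grade
  probabilities, emulating a 10-assessor panel;
* VOC tables: log-normal concentrations with a planted set of "key"
  compounds that are guaranteed to pass the VIP > 1 and OAV > 1 screen,
  and a fermentation effect multiplier applied to a subset of compounds
  in fermented samples.

One integer seed drives each generator; sub-streams are split off a
single ``numpy.random.default_rng`` in documented order so results are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flavor import CATEGORIES, VOCRecord, VOCTable
from .fuzzy import (
    DEFAULT_ATTRIBUTES,
    DEFAULT_GRADES,
    DEFAULT_GRADE_SCORES,
    DEFAULT_WEIGHTS,
    SensoryPanel,
)
from .mixture_design import MixtureDesign
from .scheffe import ResponseTable, ScheffeModel, predict_many

__all__ = [
    "SyntheticSpec",
    "gen_mixture_responses",
    "gen_sensory_counts",
    "gen_voc_table",
]

#: default measurement noise, response units: matches the magnitude of
#: the triplicate SDs reported for total phenolic content (mg GAE/mL)
DEFAULT_NOISE_SD_TPC = 0.02
#: and for lactic acid (g/L)
DEFAULT_NOISE_SD_LACTIC = 0.13


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic mixture-response experiment."""

    true_model: ScheffeModel
    design: MixtureDesign
    noise_sd: float = DEFAULT_NOISE_SD_TPC
    replicates: int = 3
    seed: int = 0
    response_name: str = "response"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if self.true_model.q != self.design.q:
            raise ValueError("model and design dimension mismatch")


def gen_mixture_responses(spec: SyntheticSpec) -> ResponseTable:
    """Simulate a response table: truth polynomial + Gaussian noise.

    Each replicate of each design point gets an independent
    Normal(0, noise_sd) error.  With ``noise_sd == 0`` the responses
    equal the model predictions exactly.
    """
    rng = np.random.default_rng(spec.seed)
    from dataclasses import replace

    design = replace(spec.design, replicates=spec.replicates)
    X = np.repeat(design.as_matrix(), spec.replicates, axis=0)
    mu = predict_many(spec.true_model, X)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=mu.shape) if spec.noise_sd > 0 else 0.0
    )
    return ResponseTable(
        design=design,
        response_name=spec.response_name,
        values=tuple(float(v) for v in mu + noise),
    )


def gen_sensory_counts(
    true_probs: Sequence[Sequence[float]],
    n_panelists: int = 10,
    seed: int = 0,
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
    grades: Sequence[str] = DEFAULT_GRADES,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    grade_scores: Sequence[float] = DEFAULT_GRADE_SCORES,
) -> SensoryPanel:
    """Draw a panel count table from known per-attribute grade probabilities.

    One multinomial(n_panelists, probs) draw per attribute row, so every
    row sums to the panel size by construction.
    """
    P = np.asarray(true_probs, dtype=float)
    if P.ndim != 2 or P.shape != (len(attributes), len(grades)):
        raise ValueError(
            f"true_probs shape {P.shape} does not match "
            f"{len(attributes)} attributes x {len(grades)} grades"
        )
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each attribute row of true_probs must be a probability vector")
    if n_panelists < 1:
        raise ValueError("n_panelists must be positive")
    rng = np.random.default_rng(seed)
    counts = tuple(
        tuple(int(c) for c in rng.multinomial(n_panelists, row)) for row in P
    )
    return SensoryPanel(
        attributes=tuple(attributes),
        grades=tuple(grades),
        counts=counts,
        weights=tuple(weights),
        grade_scores=tuple(grade_scores),
    )


def gen_voc_table(
    n_compounds: int = 60,
    samples: Sequence[str] = ("unfermented", "fermented"),
    effect: float = 1.5,
    seed: int = 0,
    n_key: int = 5,
    effect_fraction: float = 0.4,
    nd_rate: float = 0.15,
    mode: str = "gcms",
) -> tuple[VOCTable, set[str]]:
    """Simulate a volatile-compound table with planted key compounds.

    Concentrations are log-normal (median ~0.2 mg/L, spanning roughly
    two orders of magnitude, as in real headspace GC-MS tables); odor
    thresholds are log-uniform over [1e-4, 1] mg/L; a random
    ``effect_fraction`` of compounds is multiplied by ``effect`` in
    every sample after the first (the "fermented" ones); a random
    ``nd_rate`` of (compound, sample) cells is masked to ND, never for
    key compounds.

    ``n_key`` compounds are planted as ground-truth key aroma
    contributors: VIP drawn from (1, 2] and threshold set below their
    minimum concentration so OAV > 1 in every sample; all other
    compounds get VIP in [0, 1) or a threshold above their maximum
    concentration, so the VIP > 1 AND OAV > 1 screen recovers exactly
    the planted set.  Returns the table and the planted name set.

    Sub-stream order from the single seed: concentrations, effect
    subset, thresholds, VIP, ND mask.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if n_key > n_compounds:
        raise ValueError("cannot plant more key compounds than compounds")
    rng = np.random.default_rng(seed)
    samples = tuple(samples)
    n_s = len(samples)

    conc = np.exp(rng.normal(np.log(0.2), 1.0, size=(n_compounds, n_s)))
    n_eff = int(round(effect_fraction * n_compounds))
    eff_idx = rng.choice(n_compounds, size=n_eff, replace=False)
    if n_s > 1:
        conc[eff_idx, 1:] *= effect

    thresholds = np.exp(rng.uniform(np.log(1e-4), np.log(1.0), size=n_compounds))
    vip = rng.uniform(0.0, 1.0, size=n_compounds)  # sub-unity by default
    nd_mask = rng.random(size=(n_compounds, n_s)) < nd_rate

    key_idx = np.asarray(sorted(rng.choice(n_compounds, size=n_key, replace=False)))
    for i in key_idx:
        vip[i] = 1.0 + rng.uniform(0.1, 1.0)  # strictly > 1
        thresholds[i] = conc[i].min() / (1.0 + rng.uniform(0.5, 5.0))  # OAV > 1
        nd_mask[i] = False
    # non-key compounds must fail the screen: push their threshold above
    # their maximum concentration so no OAV exceeds 1
    for i in range(n_compounds):
        if i not in key_idx and thresholds[i] <= conc[i].max():
            thresholds[i] = conc[i].max() * (1.0 + rng.uniform(0.1, 2.0))

    cats = list(CATEGORIES)
    records = []
    for i in range(n_compounds):
        quant = {
            s: (None if nd_mask[i, j] else float(conc[i, j]))
            for j, s in enumerate(samples)
        }
        records.append(
            VOCRecord(
                name=f"compound_{i:03d}",
                formula="",
                category=cats[i % len(cats)],
                ri_observed=float(800 + i),
                ri_literature=float(800 + i),
                concentrations=quant if mode == "gcms" else {},
                relative_intensity=quant if mode == "gcims" else {},
                threshold=float(thresholds[i]),
                vip=float(vip[i]),
            )
        )
    table = VOCTable(records=tuple(records), samples=samples, mode=mode)
    planted = {f"compound_{i:03d}" for i in key_idx}
    return table, planted
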