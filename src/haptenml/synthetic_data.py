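"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the three kinds of real input so every pipeline
stage is testable without chemistry or downloads:

* prevalence tables — patient medians roughly uniform over the envelope
  of the printed data (0.2–10.5%), general-population medians
  zero-inflated (a seventh of substances have no background positives)
  and otherwise 0.1–3.4%;
* descriptor matrices — class-conditional Gaussians with independent
  coordinates, a controllable mean separation in a random subset of
  informative descriptors and pure-noise remainder; the closed-form
  Bayes error of the generative model is stored with the dataset;
* substance→hapten composition tables exercising every label-propagation
  rule (0-mixes, 1-mixes, inorganic exclusions).

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.stats import norm

from haptenml.dataset import EXCLUDED, HaptenIdentity, SubstanceEntry
from haptenml.epidemiology import (
    PrevalenceRecord,
    classify_ear,
    classify_eor,
    compute_ear,
    compute_eor,
)
from haptenml.featurize import DescriptorMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDescriptors",
    "generate_prevalence",
    "generate_descriptors",
    "generate_mix_table",
    "bayes_error",
]


@dataclass
class SyntheticConfig:
    """Knobs for the three generators; defaults mirror the printed data
    envelope (max patient median 10.20%, max population median 3.40%,
    7 of 50 substances with a zero population median, mixes of 2–4
    components)."""

    n_substances: int = 50
    mix_fraction: float = 0.15
    me_gen_zero_prob: float = 7.0 / 50.0
    me_acd_range: Tuple[float, float] = (0.2, 10.5)
    me_gen_range: Tuple[float, float] = (0.1, 3.4)
    n_descriptors: int = 10
    n_informative: int = 1
    class_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mix_fraction <= 1.0):
            raise ValueError("mix_fraction must be in [0, 1]")
        if not (0.0 <= self.me_gen_zero_prob <= 1.0):
            raise ValueError("me_gen_zero_prob must be in [0, 1]")
        for lo, hi in (self.me_acd_range, self.me_gen_range):
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError("ranges must be within [0, 100]")
        if self.n_descriptors < 1:
            raise ValueError("n_descriptors must be >= 1")
        if not (1 <= self.n_informative <= self.n_descriptors):
            raise ValueError("n_informative must be in [1, n_descriptors]")


def generate_prevalence(
    config: SyntheticConfig,
) -> Tuple[List[PrevalenceRecord], List[dict]]:
    """Prevalence records plus ground-truth indices and labels.

    Each substance gets a patient median drawn uniformly in
    ``me_acd_range`` and a population median that is 0 with probability
    ``me_gen_zero_prob`` and otherwise uniform in ``me_gen_range``.  The
    stored truth applies the index definitions to the drawn medians, so
    the epidemiology module must recover every label exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: List[PrevalenceRecord] = []
    truth: List[dict] = []
    for i in range(config.n_substances):
        me_acd = float(rng.uniform(*config.me_acd_range))
        if rng.random() < config.me_gen_zero_prob:
            me_gen = 0.0
        else:
            me_gen = float(rng.uniform(*config.me_gen_range))
        # three reported rates whose median is the drawn value
        spread_a = min(me_acd, 0.1)
        rates_acd = (me_acd - spread_a, me_acd, min(me_acd + spread_a, 100.0))
        if me_gen > 0:
            spread_g = min(me_gen, 0.05)
            rates_gen = (me_gen - spread_g, me_gen, min(me_gen + spread_g, 100.0))
        else:
            rates_gen = (0.0,)
        name = f"synthetic-substance-{i + 1:03d}"
        records.append(
            PrevalenceRecord(substance_name=name, rates_acd=rates_acd, rates_gen=rates_gen)
        )
        eor = compute_eor(me_acd, me_gen)
        ear = compute_ear(me_acd, me_gen)
        truth.append(
            {
                "substance_name": name,
                "me_acd": me_acd,
                "me_gen": me_gen,
                "eor": eor,
                "ear": ear,
                "label_eor": classify_eor(eor),
                "label_ear": classify_ear(ear),
            }
        )
    return records, truth


def bayes_error(class_separation: float, n_informative: int = 1) -> float:
    """Bayes error of the two-Gaussian generative model.

    With equal priors, unit within-class variance, and class means
    separated by ``class_separation`` in each of ``n_informative``
    independent coordinates, the optimal rule errs with probability
    ``Φ(−Δ/2)`` where ``Δ = class_separation · sqrt(n_informative)`` is
    the Mahalanobis distance between the class means.
    """
    delta = class_separation * math.sqrt(n_informative)
    return float(norm.cdf(-delta / 2.0))


@dataclass
class SyntheticDescriptors:
    """A generated descriptor matrix with its ground truth."""

    matrix: DescriptorMatrix
    labels: np.ndarray
    informative: List[str]
    bayes_error: float


def generate_descriptors(
    n_per_class: int, config: SyntheticConfig
) -> SyntheticDescriptors:
    """Class-conditional Gaussian descriptors with known Bayes error.

    ``n_informative`` randomly chosen descriptors have class means
    ``±class_separation/2`` (unit variance, so the means are
    ``class_separation`` pooled standard deviations apart); the rest are
    standard-normal noise in both classes.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(config.seed)
    d = config.n_descriptors
    names = [f"d{j + 1:03d}" for j in range(d)]
    informative_idx = sorted(
        rng.choice(d, size=config.n_informative, replace=False).tolist()
    )
    mu = np.zeros(d)
    mu[informative_idx] = config.class_separation / 2.0

    n = 2 * n_per_class
    labels = np.array([0] * n_per_class + [1] * n_per_class, dtype=int)
    X = rng.standard_normal((n, d))
    X[labels == 0] -= mu
    X[labels == 1] += mu
    perm = rng.permutation(n)
    X, labels = X[perm], labels[perm]
    matrix = DescriptorMatrix(
        row_ids=[f"synthetic-hapten-{i + 1:04d}" for i in range(n)],
        descriptor_names=names,
        values=X,
        provider_id=f"synthetic:sep={config.class_separation}:seed={config.seed}",
    )
    return SyntheticDescriptors(
        matrix=matrix,
        labels=labels,
        informative=[names[j] for j in informative_idx],
        bayes_error=bayes_error(config.class_separation, config.n_informative),
    )


def generate_mix_table(config: SyntheticConfig) -> List[SubstanceEntry]:
    """Substance entries exercising every label-propagation rule.

    ``mix_fraction`` of substances are mixes of 2–4 haptens; mixes are
    labeled 0 or 1 with equal probability (a 1-mix must propagate no
    records), and one inorganic single-hapten substance is appended when
    the table has room, so exclusion paths are always exercised.
    """
    rng = np.random.default_rng(config.seed)
    entries: List[SubstanceEntry] = []
    counter = 0
    for i in range(config.n_substances):
        is_mix = rng.random() < config.mix_fraction
        n_comp = int(rng.integers(2, 5)) if is_mix else 1
        comps = []
        for _ in range(n_comp):
            counter += 1
            comps.append(
                HaptenIdentity(
                    name=f"synthetic-hapten-{counter:04d}",
                    cas="n/a",
                    smiles=f"C{'C' * (counter % 5)}O",
                )
            )
        label = int(rng.integers(0, 2))
        entries.append(
            SubstanceEntry(
                substance_name=f"synthetic-substance-{i + 1:03d}",
                components=comps,
                label_eor=label,
                label_ear=label,
                organic=True,
            )
        )
    if config.n_substances >= 1:
        counter += 1
        entries.append(
            SubstanceEntry(
                substance_name="synthetic-inorganic-salt",
                components=[
                    HaptenIdentity(name=f"synthetic-hapten-{counter:04d}", smiles="")
                ],
                label_eor=1,
                label_ear=1,
                organic=False,
            )
        )
    return entries
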