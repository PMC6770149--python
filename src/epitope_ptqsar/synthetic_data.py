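"""Synthetic pair-assay tables with a known generative truth.

The generator emulates the structure of curated linear B-cell epitope
assay data at desk scale: short peptides (5-30 residues over the 20
standard amino acids), five categorical condition factors with
heavy-tailed (Zipf) category frequencies, a mildly imbalanced binary
activity class (about 1.84 intermediate records per high record), and a
query/reference pairing in which sequences recur across many records.

Labels are generated *through the real descriptor pipeline*: sequences
are turned into star-graph entropy descriptors, the ten perturbation
features are assembled in reproduction mode, and the query class is drawn
from a logistic model on the z-scored features — a linear part (mainly
the reference activity and the sequence-level entropy difference) plus an
optional product of two difference features that plants a non-linear
interaction no linear classifier can represent.  Labels are then flipped
at a small noise rate.  The logistic intercept is solved numerically so
that the expected positive rate, after noise, matches the configured
class imbalance.

Everything is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .pt_features import (
    FEATURE_COLUMNS,
    AssayRecord,
    assemble_features,
    compute_condition_means,
)
from .star_entropy import descriptor_table

__all__ = [
    "STANDARD_RESIDUES",
    "SyntheticSpec",
    "SyntheticDataset",
    "random_peptide",
    "generate_dataset",
    "nonlinear_spec",
    "separable_spec",
    "planted_importance_spec",
]

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Condition-factor vocabulary sizes, scaled down from the curated data's
#: 1448/323/15/28/505 to keep every category populated at desk scale.
DEFAULT_VOCAB_SIZES = {"org": 50, "host": 20, "proc": 15, "tech": 28, "adju": 30}

# Default signal model: moderate linear effects of the reference activity
# and the sequence-level theta_5 difference, plus a dominant interaction
# between two difference features.  The interaction is what separates
# tree ensembles from linear classifiers on this data.
DEFAULT_COEFFICIENTS = {"e_ref": 0.8, "d_theta5_seq": 0.6}
DEFAULT_INTERACTION = ("d_theta5_seq", "d_theta0_org", 3.5)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic pair-assay dataset.

    ``class_ratio`` is the target n_intermediate : n_high ratio (1.84
    mirrors the curated data's imbalance).  ``coefficients`` are logistic
    weights on z-scored features; ``interaction`` is
    ``(feature_a, feature_b, weight)`` on the product of two z-scored
    features, or ``None``.  ``noise_rate`` is the label-flip probability,
    in [0, 0.5).
    """

    n_records: int
    seed: int = 0
    length_range: tuple[int, int] = (5, 30)
    alphabet: str = STANDARD_RESIDUES
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VOCAB_SIZES)
    )
    zipf_exponent: float = 1.1
    class_ratio: float = 1.84
    ref_positive_rate: float = 0.35
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    interaction: tuple[str, str, float] | None = DEFAULT_INTERACTION
    noise_rate: float = 0.02
    n_sequences: int | None = None
    embedded: bool = False

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if self.class_ratio <= 0:
            raise ValueError("class_ratio must be positive")
        if any(v < 1 for v in self.vocab_sizes.values()):
            raise ValueError("vocabulary sizes must be positive")
        unknown = set(self.coefficients) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"coefficients on unknown features: {sorted(unknown)}")
        if self.interaction is not None:
            a, b, _ = self.interaction
            if a not in FEATURE_COLUMNS or b not in FEATURE_COLUMNS:
                raise ValueError(f"interaction on unknown features: {(a, b)}")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated records, their assembled feature table, and the truth."""

    records: tuple[AssayRecord, ...]
    features: pd.DataFrame
    truth: dict


def random_peptide(length: int, rng: np.random.Generator, alphabet: str = STANDARD_RESIDUES) -> str:
    """Uniform i.i.d. peptide of the given length."""
    if length < 1:
        raise ValueError(f"peptide length must be >= 1, got {length}")
    return "".join(rng.choice(list(alphabet), size=length))


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1) ** exponent
    return weights / weights.sum()


def _sequence_pool(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    n_pool = spec.n_sequences or max(30, spec.n_records // 20)
    pool: list[str] = []
    seen: set[str] = set()
    lo, hi = spec.length_range
    while len(pool) < n_pool:
        seq = random_peptide(int(rng.integers(lo, hi + 1)), rng, spec.alphabet)
        if seq not in seen:
            seen.add(seq)
            pool.append(seq)
    return pool


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a pair-assay table and labels from the configured truth.

    The pipeline: sample a pool of distinct sequences and reuse them
    across records (as real assay tables do); sample Zipf-skewed condition
    categories; run the actual descriptor and perturbation-feature code;
    draw the query class from the logistic truth; flip labels at the noise
    rate.  Returns the records (with labels filled in), the feature table,
    and a truth dict recording every parameter and the solved intercept.
    """
    rng = np.random.default_rng(spec.seed)
    pool = _sequence_pool(spec, rng)
    theta = descriptor_table(pool, embedded=spec.embedded)

    categories = {
        factor: [f"{factor.upper()}_{i:04d}" for i in range(size)]
        for factor, size in spec.vocab_sizes.items()
    }
    cat_probs = {
        factor: _zipf_probs(size, spec.zipf_exponent)
        for factor, size in spec.vocab_sizes.items()
    }

    n = spec.n_records
    query_idx = rng.integers(0, len(pool), size=n)
    ref_idx = rng.integers(0, len(pool), size=n)
    e_ref = rng.binomial(1, spec.ref_positive_rate, size=n)
    factor_draws = {
        factor: rng.choice(categories[factor], size=n, p=cat_probs[factor])
        for factor in categories
    }
    records = [
        AssayRecord(
            query_seq=pool[query_idx[i]],
            ref_seq=pool[ref_idx[i]],
            ref_activity=int(e_ref[i]),
            query_activity=0,  # placeholder until the truth assigns labels
            conditions={f: factor_draws[f][i] for f in factor_draws},
        )
        for i in range(n)
    ]

    means = compute_condition_means(records, theta)
    features = assemble_features(records, theta, means)

    z = {c: _zscore(features[c].to_numpy(dtype=float)) for c in FEATURE_COLUMNS}
    score = np.zeros(n)
    for name, coef in spec.coefficients.items():
        score += coef * z[name]
    if spec.interaction is not None:
        a, b, w = spec.interaction
        score += w * z[a] * z[b]

    # Positive rate implied by the class ratio, corrected for label noise
    # so the post-noise expectation hits the target.
    target = 1.0 / (1.0 + spec.class_ratio)
    target_pre = (target - spec.noise_rate) / (1.0 - 2.0 * spec.noise_rate)
    if not (0.0 < target_pre < 1.0):
        raise ValueError(
            f"class ratio {spec.class_ratio} unreachable at noise rate "
            f"{spec.noise_rate}"
        )
    intercept = brentq(lambda b0: expit(b0 + score).mean() - target_pre, -60.0, 60.0)

    labels = rng.binomial(1, expit(intercept + score))
    flips = rng.random(n) < spec.noise_rate
    labels = np.where(flips, 1 - labels, labels)

    features[features.columns[-1]] = labels.astype(int)
    records = tuple(
        AssayRecord(
            query_seq=r.query_seq,
            ref_seq=r.ref_seq,
            ref_activity=r.ref_activity,
            query_activity=int(labels[i]),
            conditions=r.conditions,
        )
        for i, r in enumerate(records)
    )

    truth = {
        "n_records": n,
        "seed": spec.seed,
        "length_range": list(spec.length_range),
        "alphabet": spec.alphabet,
        "vocab_sizes": dict(spec.vocab_sizes),
        "zipf_exponent": spec.zipf_exponent,
        "class_ratio_target": spec.class_ratio,
        "ref_positive_rate": spec.ref_positive_rate,
        "coefficients": dict(spec.coefficients),
        "interaction": list(spec.interaction) if spec.interaction else None,
        "noise_rate": spec.noise_rate,
        "n_sequences": len(pool),
        "embedded": spec.embedded,
        "intercept": float(intercept),
        "achieved_positive_rate": float(labels.mean()),
    }
    return SyntheticDataset(records=records, features=features, truth=truth)


def nonlinear_spec(n_records: int, seed: int = 0) -> SyntheticSpec:
    """Interaction-dominated truth: tree ensembles should beat linear models."""
    return SyntheticSpec(n_records=n_records, seed=seed)


def separable_spec(n_records: int, seed: int = 0) -> SyntheticSpec:
    """Strong noise-free linear truth: every competent method scores high."""
    return SyntheticSpec(
        n_records=n_records,
        seed=seed,
        coefficients={"e_ref": 3.0, "d_theta5_seq": 4.0, "q_theta5_seq": 2.0},
        interaction=None,
        noise_rate=0.0,
    )


def planted_importance_spec(n_records: int, seed: int = 0) -> SyntheticSpec:
    """Signal concentrated on the reference activity, then d_theta5_seq.

    Used to check that impurity-based importances recover the planted
    ordering: e_ref first, d_theta5_seq among the top features.
    """
    return SyntheticSpec(
        n_records=n_records,
        seed=seed,
        coefficients={"e_ref": 3.0, "d_theta5_seq": 1.0},
        interaction=None,
        noise_rate=0.05,
    )
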