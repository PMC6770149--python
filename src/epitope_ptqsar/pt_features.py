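"""Perturbation-theory feature construction for query/reference epitope pairs.

Each assay record pairs a query peptide with a reference peptide of known
activity class under five categorical experimental-condition factors
(epitope organism, host organism, in-vivo process, experimental technique,
adjuvant additive); a sixth implicit factor, ``Seq``, is the whole set of
sequences.  For a condition factor ``c_j``, the perturbation of a
descriptor ``theta_k`` is its deviation from the mean descriptor of all
records sharing that record's category of ``c_j`` (for ``Seq``, deviation
from the grand mean).  Difference features subtract the reference
perturbation from the query perturbation under the identical category.

The model's input table has exactly ten features, in this order::

    e_ref, q_theta5_seq, q_theta0_org, q_theta0_tech, d_theta5_seq,
    d_theta0_host, d_theta0_adju, d_theta0_proc, d_theta0_org, d_theta0_tech

followed by the binary label (query activity class: positive-high = 1,
positive-intermediate = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .star_entropy import validate_peptide

__all__ = [
    "FACTORS",
    "FEATURE_COLUMNS",
    "LABEL_COLUMN",
    "AssayRecord",
    "ConditionMeans",
    "MissingDescriptorError",
    "UnseenCategoryError",
    "compute_condition_means",
    "perturbation",
    "assemble_features",
    "deduplicate",
    "build_feature_table",
]

#: The five explicit condition factors, in canonical column order.
FACTORS = ("org", "host", "proc", "tech", "adju")

#: The ten model features, in canonical order.
FEATURE_COLUMNS = (
    "e_ref",
    "q_theta5_seq",
    "q_theta0_org",
    "q_theta0_tech",
    "d_theta5_seq",
    "d_theta0_host",
    "d_theta0_adju",
    "d_theta0_proc",
    "d_theta0_org",
    "d_theta0_tech",
)

LABEL_COLUMN = "label"


class MissingDescriptorError(KeyError):
    """A record's sequence has no entry in the descriptor map."""


class UnseenCategoryError(KeyError):
    """A record carries a condition category absent from the fitted means."""


@dataclass(frozen=True)
class AssayRecord:
    """One query/reference epitope pair with its assay conditions.

    ``ref_activity`` and ``query_activity`` are binary classes
    (positive-high = 1, positive-intermediate = 0); ``query_activity`` is
    the modeling label.  ``conditions`` maps each factor in
    :data:`FACTORS` to a non-empty category identifier.
    """

    query_seq: str
    ref_seq: str
    ref_activity: int
    query_activity: int
    conditions: Mapping[str, str]

    def __post_init__(self) -> None:
        validate_peptide(self.query_seq)
        validate_peptide(self.ref_seq)
        for name, value in (
            ("ref_activity", self.ref_activity),
            ("query_activity", self.query_activity),
        ):
            if value not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {value!r}")
        for factor in FACTORS:
            cat = self.conditions.get(factor)
            if not isinstance(cat, str) or not cat:
                raise ValueError(
                    f"condition factor {factor!r} must be a non-empty string, "
                    f"got {cat!r}"
                )


@dataclass
class ConditionMeans:
    """Per-category mean descriptor vectors, plus the grand mean (``Seq``).

    Means are arithmetic means of the *query* descriptor vectors of the
    records used to fit them, one vector per observed category of each
    factor; the ``Seq`` factor contributes a single grand mean.
    """

    grand: np.ndarray
    per_factor: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def category_mean(self, factor: str, category: str) -> np.ndarray:
        try:
            return self.per_factor[factor][category]
        except KeyError:
            raise UnseenCategoryError(
                f"category {category!r} of factor {factor!r} was not observed "
                "when the condition means were fitted"
            ) from None


def _lookup_theta(theta: Mapping[str, np.ndarray], seq: str) -> np.ndarray:
    try:
        return np.asarray(theta[seq], dtype=float)
    except KeyError:
        raise MissingDescriptorError(
            f"sequence {seq!r} has no entry in the descriptor map"
        ) from None


def compute_condition_means(
    records: Sequence[AssayRecord], theta: Mapping[str, np.ndarray]
) -> ConditionMeans:
    """Fit category means of the query descriptor vectors.

    For every factor and every category observed in ``records``, the mean
    theta vector over the query sequences of the records carrying that
    category; the ``Seq`` factor yields the grand mean over all records.
    Deterministic and permutation-invariant.
    """
    if not records:
        raise ValueError("cannot compute condition means from zero records")
    q_theta = np.stack([_lookup_theta(theta, r.query_seq) for r in records])
    sums: dict[str, dict[str, np.ndarray]] = {f: {} for f in FACTORS}
    counts: dict[str, dict[str, int]] = {f: {} for f in FACTORS}
    for row, record in zip(q_theta, records):
        for factor in FACTORS:
            cat = record.conditions[factor]
            if cat in sums[factor]:
                sums[factor][cat] = sums[factor][cat] + row
                counts[factor][cat] += 1
            else:
                sums[factor][cat] = row.copy()
                counts[factor][cat] = 1
    per_factor = {
        factor: {
            cat: sums[factor][cat] / counts[factor][cat] for cat in sums[factor]
        }
        for factor in FACTORS
    }
    return ConditionMeans(grand=q_theta.mean(axis=0), per_factor=per_factor)


def perturbation(theta_k: float, mean_k: float) -> float:
    """Perturbation of a descriptor: its deviation from a condition mean."""
    return theta_k - mean_k


def assemble_features(
    records: Sequence[AssayRecord],
    theta: Mapping[str, np.ndarray],
    means: ConditionMeans,
    on_unseen: str = "error",
) -> pd.DataFrame:
    """Assemble the 10-feature perturbation table, one row per record.

    Query perturbation features deviate the query descriptors from the
    record's category mean; difference features subtract the reference
    perturbation computed with the *same* category mean, so
    ``d_theta_k = q_theta_k - r_theta_k`` algebraically and difference
    features are antisymmetric under query/reference swap.

    ``on_unseen`` controls records whose category was not observed when
    ``means`` was fitted (only possible when means come from a training
    subset): ``"error"`` raises, ``"grand"`` falls back to the grand mean.
    """
    if on_unseen not in ("error", "grand"):
        raise ValueError(f"on_unseen must be 'error' or 'grand', got {on_unseen!r}")
    rows = np.empty((len(records), len(FEATURE_COLUMNS) + 1))
    for i, rec in enumerate(records):
        q = _lookup_theta(theta, rec.query_seq)
        r = _lookup_theta(theta, rec.ref_seq)
        cat_mean: dict[str, np.ndarray] = {}
        for factor in FACTORS:
            try:
                cat_mean[factor] = means.category_mean(factor, rec.conditions[factor])
            except UnseenCategoryError:
                if on_unseen == "error":
                    raise
                cat_mean[factor] = means.grand

        def d(k: int, mean_vec: np.ndarray) -> float:
            return perturbation(q[k], mean_vec[k]) - perturbation(r[k], mean_vec[k])

        rows[i] = (
            rec.ref_activity,
            perturbation(q[5], means.grand[5]),
            perturbation(q[0], cat_mean["org"][0]),
            perturbation(q[0], cat_mean["tech"][0]),
            d(5, means.grand),
            d(0, cat_mean["host"]),
            d(0, cat_mean["adju"]),
            d(0, cat_mean["proc"]),
            d(0, cat_mean["org"]),
            d(0, cat_mean["tech"]),
            rec.query_activity,
        )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + [LABEL_COLUMN]).astype(
        {"e_ref": int, LABEL_COLUMN: int}
    )


def deduplicate(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows identical in all ten features and the label, keeping first.

    Equality is assessed on the row serialized with features at six decimal
    places, which makes the comparison robust to float noise and
    reproducible across platforms.  Row order is otherwise preserved, so
    "keep first" is well defined; the operation is idempotent.
    """
    cols = list(FEATURE_COLUMNS) + [LABEL_COLUMN]
    keys = [
        ",".join(f"{v:.6f}" for v in row)
        for row in table[cols].to_numpy(dtype=float)
    ]
    keep = ~pd.Series(keys, index=table.index).duplicated()
    return table.loc[keep].reset_index(drop=True)


def build_feature_table(
    records: Sequence[AssayRecord],
    theta: Mapping[str, np.ndarray],
    dedup: bool = False,
) -> pd.DataFrame:
    """Reproduction-mode pipeline: fit means on all records, then assemble.

    This matches how a single precomputed feature table is built; for a
    leakage-safe evaluation fit :func:`compute_condition_means` on the
    training subset only and call :func:`assemble_features` per split.
    """
    means = compute_condition_means(records, theta)
    table = assemble_features(records, theta, means)
    return deduplicate(table) if dedup else table


def fold_feature_tables(
    records: Sequence[AssayRecord],
    theta: Mapping[str, np.ndarray],
    train_idx: Iterable[int],
    test_idx: Iterable[int],
    on_unseen: str = "error",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leakage-safe split assembly: means fitted on the training subset only."""
    train = [records[i] for i in train_idx]
    test = [records[i] for i in test_idx]
    means = compute_condition_means(train, theta)
    return (
        assemble_features(train, theta, means, on_unseen=on_unseen),
        assemble_features(test, theta, means, on_unseen=on_unseen),
    )
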