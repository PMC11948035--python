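"""Bulk-transcriptome signature analyses.

Single-sample GSEA (ssGSEA) signature scores for immune and fibroblast gene
sets, gene-set construction from single-cell cluster markers, gene-signature
Spearman correlation, and median-split Kaplan-Meier survival comparison with
a two-group log-rank test.

The ssGSEA variant is the rank-weighted running-sum statistic: within each
sample, genes are ranked by expression (average ranks on ties) and the
enrichment score is the summed difference between the weighted cumulative
distribution of in-set genes (weight = rank^alpha, alpha = 0.25) and the
uniform cumulative distribution of out-of-set genes, walking the genes from
highest to lowest expression. Scores are rank-based, hence invariant to any
strictly increasing per-sample transform of the expression values. An
optional min-max normalization across samples is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .variant_io import NeofunnelError, RecordValidationError, TableFormatError

log = logging.getLogger(__name__)

DEFAULT_SSGSEA_ALPHA = 0.25
CD8_SIGNATURE_GENES = ("CD8A", "CD8B")
CD4_GENE = "CD4"


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise RecordValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise RecordValidationError(f"gene set {self.name!r} has duplicate genes")


@dataclass(frozen=True)
class SignatureScore:
    sample: str
    set_name: str
    score: float


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time: float  # months
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise RecordValidationError(
                f"{self.sample}: survival time must be positive, got {self.time}"
            )


# ---------------------------------------------------------------------------
# Gene-set construction
# ---------------------------------------------------------------------------


def top_marker_gene_set(
    markers: pd.DataFrame, cluster: str, n: int = 20, name: str | None = None
) -> GeneSet:
    """The n cluster markers with the highest fold change.

    ``markers`` needs columns gene / cluster / fold_change. Ties at the
    cutoff break alphabetically (first kept); fewer than n available markers
    yield all of them with a warning.
    """
    for col in ("gene", "cluster", "fold_change"):
        if col not in markers.columns:
            raise TableFormatError(f"marker table missing column {col!r}")
    sub = markers[markers["cluster"] == cluster]
    if sub.empty:
        raise RecordValidationError(f"no marker rows for cluster {cluster!r}")
    if len(sub) < n:
        log.warning(
            "cluster %s: only %d markers available (requested %d)",
            cluster, len(sub), n,
        )
    ordered = sub.sort_values(
        ["fold_change", "gene"], ascending=[False, True], kind="mergesort"
    )
    genes = tuple(ordered["gene"].head(n))
    return GeneSet(name=name or f"{cluster}_top{n}", genes=genes)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise RecordValidationError(f"duplicate gene symbol in matrix: {dup!r}")
    if matrix.shape[0] < 2:
        raise RecordValidationError("expression matrix needs >= 2 genes")


def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Weighted running-sum enrichment for one sample's expression vector."""
    n = values.size
    n_in = int(in_set.sum())
    n_out = n - n_in
    if n_out == 0:
        raise RecordValidationError("gene set covers the whole matrix")
    ranks = stats.rankdata(values)  # ascending, average ties
    order = np.argsort(-values, kind="stable")  # highest expression first
    in_ordered = in_set[order]
    weights = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    total_w = weights.sum()
    cdf_in = np.cumsum(weights) / total_w
    cdf_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_score(
    matrix: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> list[SignatureScore]:
    """Per-sample ssGSEA enrichment of ``gene_set`` in ``matrix``.

    ``matrix`` is genes x samples. At least one set gene must be present.
    With ``normalize`` the scores are min-max scaled across samples.
    """
    _check_matrix(matrix)
    present = [g for g in gene_set.genes if g in matrix.index]
    if not present:
        raise RecordValidationError(
            f"no gene of set {gene_set.name!r} present in the matrix"
        )
    if len(present) < len(gene_set.genes):
        log.warning(
            "set %s: %d/%d genes present in matrix",
            gene_set.name, len(present), len(gene_set.genes),
        )
    in_set = matrix.index.isin(present).astype(bool)
    values = matrix.to_numpy(dtype=float)
    constant = np.all(values == values[0, :], axis=0)
    if constant.any():
        log.warning(
            "%d sample(s) have constant expression (ties everywhere)",
            int(constant.sum()),
        )
    scores = np.array(
        [_ssgsea_sample(values[:, j], in_set, alpha) for j in range(values.shape[1])]
    )
    if normalize:
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return [
        SignatureScore(sample=str(s), set_name=gene_set.name, score=float(v))
        for s, v in zip(matrix.columns, scores)
    ]


def cd8_infiltration_score(
    matrix: pd.DataFrame, alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> list[SignatureScore]:
    """CD8+ T-cell infiltration: ssGSEA of the {CD8A, CD8B} signature."""
    if not any(g in matrix.index for g in CD8_SIGNATURE_GENES):
        raise RecordValidationError(
            "neither CD8A nor CD8B present in the expression matrix"
        )
    gene_set = GeneSet(name="CD8_T", genes=CD8_SIGNATURE_GENES)
    return ssgsea_score(matrix, gene_set, alpha=alpha, normalize=normalize)


def cd4_expression(matrix: pd.DataFrame) -> pd.Series:
    """CD4+ T-cell infiltration proxy: the raw CD4 expression row.

    Deliberately not a set score — a single-gene signature would reduce to a
    monotone function of the same values anyway.
    """
    if CD4_GENE not in matrix.index:
        raise RecordValidationError("CD4 absent from the expression matrix")
    return matrix.loc[CD4_GENE]


def scores_to_series(scores: Sequence[SignatureScore]) -> pd.Series:
    return pd.Series(
        {s.sample: s.score for s in scores},
        name=scores[0].set_name if scores else None,
    )


# ---------------------------------------------------------------------------
# Correlation and survival
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman: inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("spearman: need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise NeofunnelError("spearman: correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def median_stratify(
    scores: Mapping[str, float] | Sequence[SignatureScore],
) -> tuple[list[str], list[str]]:
    """Split samples at the median score: (> median -> high, <= median -> low).

    Ties at the median go to the low group, keeping the split deterministic.
    """
    if not isinstance(scores, Mapping):
        scores = {s.sample: s.score for s in scores}
    if len(scores) < 2:
        raise ValueError("median_stratify: need >= 2 samples")
    values = np.array(list(scores.values()), dtype=float)
    if np.all(values == values[0]):
        raise NeofunnelError(
            "median_stratify: all scores identical; stratification degenerate"
        )
    cutoff = float(np.median(values))
    high = [s for s, v in scores.items() if v > cutoff]
    low = [s for s, v in scores.items() if v <= cutoff]
    return high, low


def km_logrank(
    groups: tuple[Sequence[str], Sequence[str]],
    survival: Sequence[SurvivalRecord],
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns ({'high': curve, 'low': curve}, chi2, p) where each curve is a
    step function (columns ``time``, ``survival``) and p comes from the
    chi-square(1) tail of the log-rank statistic, no continuity correction.
    """
    by_sample = {r.sample: r for r in survival}
    group_records: list[list[SurvivalRecord]] = []
    for label, ids in zip(("high", "low"), groups):
        if len(ids) == 0:
            raise NeofunnelError(f"km_logrank: empty {label} group")
        missing = [s for s in ids if s not in by_sample]
        if missing:
            raise NeofunnelError(
                f"km_logrank: no survival record for sample(s) {missing[:3]}"
            )
        group_records.append([by_sample[s] for s in ids])
    if not any(r.event for recs in group_records for r in recs):
        raise NeofunnelError("km_logrank: no event observed in either group")

    curves: dict[str, pd.DataFrame] = {}
    for label, recs in zip(("high", "low"), group_records):
        kmf = KaplanMeierFitter()
        kmf.fit(
            durations=[r.time for r in recs],
            event_observed=[r.event for r in recs],
            label=label,
        )
        curves[label] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_[label].to_numpy(dtype=float),
            }
        )
    high, low = group_records
    result = logrank_test(
        durations_A=[r.time for r in high],
        durations_B=[r.time for r in low],
        event_observed_A=[r.event for r in high],
        event_observed_B=[r.event for r in low],
    )
    return curves, float(result.test_statistic), float(result.p_value)


# ---------------------------------------------------------------------------
# I/O for the module's external formats
# ---------------------------------------------------------------------------


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV, first column the gene symbol."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_matrix(df)
    return df


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}: GMT line needs name, description and >= 1 gene"
                )
            sets.append(GeneSet(name=fields[0], genes=tuple(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


def read_survival_table(path) -> list[SurvivalRecord]:
    """TSV with columns sample, time (months), event (0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing survival column {col!r}")
    records = []
    for _, row in df.iterrows():
        event_raw = str(row["event"]).strip().lower()
        if event_raw in ("1", "true"):
            event = True
        elif event_raw in ("0", "false"):
            event = False
        else:
            raise RecordValidationError(
                f"{row['sample']}: event value {row['event']!r} not boolean"
            )
        records.append(
            SurvivalRecord(sample=row["sample"], time=float(row["time"]), event=event)
        )
    return records


def write_scores_table(scores: Sequence[SignatureScore], path) -> None:
    pd.DataFrame(
        [{"sample": s.sample, "set_name": s.set_name, "score": s.score} for s in scores]
    ).to_csv(path, sep="\t", index=False)
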