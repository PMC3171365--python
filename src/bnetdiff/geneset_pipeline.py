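"""Gene-set analysis driver: file formats, per-set tests and reporting.

Reads GSEA-style inputs (GCT v1.2 expression matrix, two-class CLS
phenotype labels, GMT gene-set collection), runs the network-equality
permutation test — fixed-length or SPRT-stopped — on every retained gene
set, BH-adjusts the raw p-values across sets, and writes a TSV report.
Auxiliary per-set diagnostics mirror the companion analyses a practitioner
runs next to the network test: a sum-of-squared-t differential-expression
statistic in the same permutation engine, a per-gene t screen, and
per-pair correlation-equality tables via the Fisher z transform.

Expression values are taken as-is: no log-scaling, normalization or
probe collapsing is applied — preprocess upstream.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gaussian_bn import ExpressionSample
from .sequential_mtp import (
    StoppingConfig,
    adjust_step_up,
    bh_rule,
    stopped_permutation_test,
)
from .two_sample_test import TwoSampleData, fixed_permutation_test

__all__ = [
    "FormatError",
    "MoreThanTwoClassesError",
    "GeneSetCollection",
    "GeneSetResultRow",
    "CorrelationPairRow",
    "AnalysisConfig",
    "read_gct",
    "read_tsv_expression",
    "write_gct",
    "read_cls",
    "write_cls",
    "read_gmt",
    "run_geneset_analysis",
    "sum_squared_t_statistic",
    "per_gene_t_screen",
    "correlation_difference_table",
    "write_results",
]

logger = logging.getLogger("bnetdiff")

#: clamp on |t| for degenerate zero-pooled-variance genes in sum_squared_t
T_CLAMP = 1e6


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


class MoreThanTwoClassesError(ValueError):
    """The phenotype file declares more than two classes."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene-id sets, e.g. parsed from a GMT file."""

    sets: dict[str, tuple[str, ...]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class GeneSetResultRow:
    """One gene set's test outcome (one row of the output table)."""

    set_name: str
    size_declared: int
    size_used: int
    statistic: float
    p_raw: float
    p_adjusted: float
    tau: int
    stopped_early: bool
    note: str = ""


@dataclass(frozen=True)
class CorrelationPairRow:
    """Within-set gene pair with per-group correlations and equality p-value."""

    gene_a: str
    gene_b: str
    r_group1: float
    r_group2: float
    p_diff: float


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a gene-set batch run.

    ``B`` is the fixed replicate count and, in stopped mode, the SPRT
    truncation bound — the stopped procedure is then embedded in the fixed
    one replicate-for-replicate.
    """

    mode: str = "fixed"  # "fixed" | "stopped"
    B: int = 5000
    stopping: StoppingConfig = field(default_factory=StoppingConfig)
    statistic: str = "mlrt"  # "mlrt" | "sumt2"
    permutation: str = "balanced"
    early_p: str = "one"
    fdr_level: float = 0.25
    min_set_size: int = 5
    max_set_size: int = 500
    seed: int = 0


# ---------------------------------------------------------------------------
# File formats


def read_gct(path) -> ExpressionSample:
    """Parse a GCT v1.2 expression file into an ExpressionSample.

    Rows are genes and columns samples on disk; the returned matrix is
    transposed to samples x genes.  Duplicate gene ids keep the first
    occurrence (with a warning).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#1.2"):
        raise FormatError("missing GCT version line '#1.2'", line=1)
    try:
        n_genes, n_samples = (int(v) for v in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise FormatError("malformed dimensions line", line=2) from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0].lower() != "name":
        raise FormatError("header must start with Name<TAB>Description", line=3)
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"dimensions line declares {n_samples} samples, header has {len(sample_ids)}",
            line=3,
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise FormatError(
            f"dimensions line declares {n_genes} genes, file has {len(body)} data rows",
            line=2,
        )
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for k, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != n_samples + 2:
            raise FormatError(
                f"expected {n_samples + 2} fields, got {len(parts)}", line=4 + k
            )
        name = parts[0]
        if name in seen:
            logger.warning("duplicate gene id %r; keeping first occurrence", name)
            continue
        try:
            rows.append([float(v) for v in parts[2:]])
        except ValueError:
            raise FormatError("non-numeric expression value", line=4 + k) from None
        seen.add(name)
        gene_ids.append(name)
    values = np.array(rows, dtype=float).T
    return ExpressionSample(values, tuple(gene_ids), tuple(sample_ids))


def read_tsv_expression(path) -> ExpressionSample:
    """Plain TSV fallback: header of sample ids, one gene per row."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        logger.warning("duplicate gene ids in TSV; keeping first occurrences")
        frame = frame[~frame.index.duplicated(keep="first")]
    return ExpressionSample(
        frame.to_numpy(dtype=float).T,
        tuple(str(g) for g in frame.index),
        tuple(str(s) for s in frame.columns),
    )


def write_gct(expr: ExpressionSample, path) -> None:
    """Write an ExpressionSample as GCT v1.2 (genes x samples on disk)."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.p}\t{expr.n}\n")
        fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
        for j, gene in enumerate(expr.variable_ids):
            vals = "\t".join(repr(float(v)) for v in expr.values[:, j])
            fh.write(f"{gene}\tna\t{vals}\n")


def read_cls(path) -> np.ndarray:
    """Parse a two-class CLS phenotype file into binary labels.

    The first class token to occur is mapped to 1 (group A), the second
    to 0 (group B).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError("CLS file needs counts, class-name and label lines")
    head = lines[0].split()
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except (IndexError, ValueError):
        raise FormatError("malformed CLS counts line", line=1) from None
    if n_classes != 2:
        raise MoreThanTwoClassesError(
            f"two-sample test requires exactly 2 classes, CLS declares {n_classes}"
        )
    if not lines[1].startswith("#"):
        raise FormatError("second CLS line must start with '#'", line=2)
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"counts line declares {n_samples} samples, label line has {len(tokens)}",
            line=3,
        )
    order: list[str] = []
    for tok in tokens:
        if tok not in order:
            order.append(tok)
    if len(order) != 2:
        raise MoreThanTwoClassesError(
            f"label line contains {len(order)} distinct labels"
        )
    return np.array([1 if tok == order[0] else 0 for tok in tokens], dtype=int)


def write_cls(labels: np.ndarray, path, names: tuple[str, str] = ("A", "B")) -> None:
    """Write binary labels (1 = first class) as a two-class CLS file."""
    labels = np.asarray(labels, dtype=int)
    with open(path, "w") as fh:
        fh.write(f"{labels.size} 2 1\n")
        fh.write(f"# {names[0]} {names[1]}\n")
        fh.write(" ".join(names[0] if v == 1 else names[1] for v in labels) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, gene ids...)."""
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for k, ln in enumerate(lines):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError("GMT line needs name, description and >= 1 gene", line=k + 1)
        name = parts[0]
        genes: list[str] = []
        seen: set[str] = set()
        for g in parts[2:]:
            if not g:
                continue
            if g in seen:
                logger.warning("duplicate gene %r in set %r removed", g, name)
                continue
            seen.add(g)
            genes.append(g)
        if name in sets:
            raise FormatError(f"duplicate set name {name!r}", line=k + 1)
        sets[name] = tuple(genes)
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets=sets, provenance=str(path))


# ---------------------------------------------------------------------------
# Batch analysis


def _set_seed(master_seed: int, set_name: str) -> int:
    """Deterministic per-set seed from (master seed, set name hash)."""
    return zlib.crc32(f"{master_seed}:{set_name}".encode()) % (2**31)


def run_geneset_analysis(
    expr: ExpressionSample,
    labels: np.ndarray,
    collection: GeneSetCollection,
    config: AnalysisConfig,
) -> list[GeneSetResultRow]:
    """Test every retained gene set for network equality between phenotypes.

    For each set, the expression matrix is restricted to the set's genes
    found in it; sets whose analyzed size falls outside
    [min_set_size, max_set_size] are skipped.  Raw p-values are
    BH-adjusted across all sets that produced one.  In stopped mode the
    truncation bound is ``config.B`` and the p-value fed to BH follows
    ``config.early_p``.  Rows are sorted by (p_raw, set_name); skipped or
    failed sets appear at the end with a note.
    """
    labels = np.asarray(labels, dtype=int)
    gene_index: dict[str, int] = {}
    for j, g in enumerate(expr.variable_ids):
        gene_index.setdefault(g, j)
    stopping = replace(config.stopping, n_max=config.B)

    tested: list[GeneSetResultRow] = []
    skipped: list[GeneSetResultRow] = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        idx = [gene_index[g] for g in genes if g in gene_index]
        size_used = len(idx)

        def skip(reason: str) -> None:
            logger.info("set %s skipped: %s", name, reason)
            skipped.append(
                GeneSetResultRow(
                    set_name=name,
                    size_declared=len(genes),
                    size_used=size_used,
                    statistic=math.nan,
                    p_raw=math.nan,
                    p_adjusted=math.nan,
                    tau=0,
                    stopped_early=False,
                    note=f"skipped: {reason}",
                )
            )

        if not (config.min_set_size <= size_used <= config.max_set_size):
            skip(
                f"{size_used} genes in matrix outside "
                f"[{config.min_set_size}, {config.max_set_size}]"
            )
            continue
        seed = _set_seed(config.seed, name)
        try:
            data = TwoSampleData(expr.subset_variables(idx), labels)
            if config.mode == "fixed":
                res = fixed_permutation_test(
                    data,
                    B=config.B,
                    seed=seed,
                    statistic=config.statistic,
                    permutation=config.permutation,
                )
                p_raw, tau, early, stat = res.p_value, res.B, False, res.T_obs
            elif config.mode == "stopped":
                res = stopped_permutation_test(
                    data,
                    stopping,
                    seed=seed,
                    statistic=config.statistic,
                    permutation=config.permutation,
                    early_p=config.early_p,
                )
                p_raw, tau, early = res.p_value, res.tau, res.stopped_early
                stat = math.nan
            else:
                raise ValueError(f"unknown mode: {config.mode!r}")
        except Exception as err:  # per-set failure must not abort the batch
            skip(f"{type(err).__name__}: {err}")
            continue
        tested.append(
            GeneSetResultRow(
                set_name=name,
                size_declared=len(genes),
                size_used=size_used,
                statistic=float(stat),
                p_raw=float(p_raw),
                p_adjusted=math.nan,
                tau=int(tau),
                stopped_early=bool(early),
                note="",
            )
        )

    if tested:
        mtp = adjust_step_up(
            [row.p_raw for row in tested], bh_rule, alpha=config.fdr_level, method="BH"
        )
        tested = [
            replace(row, p_adjusted=float(adj))
            for row, adj in zip(tested, mtp.adjusted)
        ]
    tested.sort(key=lambda r: (r.p_raw, r.set_name))
    skipped.sort(key=lambda r: r.set_name)
    return tested + skipped


# ---------------------------------------------------------------------------
# Companion statistics


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column pooled-variance two-sample t statistics (clamped)."""
    n1, n2 = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0.0
    if np.any(degenerate):
        logger.warning(
            "%d gene(s) with zero pooled variance; |t| clamped to %g",
            int(degenerate.sum()),
            T_CLAMP,
        )
        t[degenerate & (diff == 0.0)] = 0.0
        t[degenerate & (diff != 0.0)] = np.sign(diff[degenerate & (diff != 0.0)]) * T_CLAMP
    return t


def sum_squared_t_statistic(data: TwoSampleData) -> float:
    """Sum over genes of squared pooled-variance t statistics.

    A pure differential-expression statistic used as a drop-in comparator
    in the same balanced-permutation engine: blind to coexpression change,
    sensitive to mean shifts.
    """
    idx_a, idx_b = data.group_indices()
    x = data.pooled.values
    t = _pooled_t(x[idx_a], x[idx_b])
    return float(np.sum(t * t))


def per_gene_t_screen(expr: ExpressionSample, labels: np.ndarray) -> pd.DataFrame:
    """Two-sided pooled-variance t test per gene with BH adjustment.

    Returns a DataFrame (gene, t, p_raw, p_adjusted, constant) sorted by
    raw p-value; constant genes get p = 1 and a flag.
    """
    labels = np.asarray(labels, dtype=int)
    idx_a, idx_b = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    a, b = expr.values[idx_a], expr.values[idx_b]
    n1, n2 = a.shape[0], b.shape[0]
    t = _pooled_t(a, b)
    constant = (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) == 0.0
    df = n1 + n2 - 2
    p_raw = 2.0 * sps.t.sf(np.abs(t), df)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    p_raw[constant] = 1.0
    mtp = adjust_step_up(p_raw, bh_rule)
    frame = pd.DataFrame(
        {
            "gene": expr.variable_ids,
            "t": t,
            "p_raw": p_raw,
            "p_adjusted": mtp.adjusted,
            "constant": constant,
        }
    )
    return frame.sort_values(["p_raw", "gene"], kind="stable").reset_index(drop=True)


def correlation_difference_table(
    expr: ExpressionSample,
    labels: np.ndarray,
    gene_set,
    top_k: int = 10,
    reference: str = "A",
) -> list[CorrelationPairRow]:
    """Per-pair correlation-equality tests within a gene set.

    For every gene pair in the set (restricted to genes present in the
    matrix), computes the correlation in each group and a two-sided
    equality p-value from the Fisher variance-stabilizing transform:
    z = atanh(r), statistic (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)).
    Rows are ranked by |r| in the reference group (descending, ties broken
    lexicographically on the pair) and the top_k returned.  r_group1
    always refers to the reference group.
    """
    labels = np.asarray(labels, dtype=int)
    idx_a, idx_b = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    if reference == "B":
        idx_a, idx_b = idx_b, idx_a
    elif reference != "A":
        raise ValueError("reference must be 'A' or 'B'")
    n1, n2 = idx_a.size, idx_b.size
    if n1 < 5 or n2 < 5:
        raise ValueError("correlation comparison needs >= 5 samples per group")
    gene_index = {g: j for j, g in enumerate(expr.variable_ids)}
    genes = sorted(g for g in gene_set if g in gene_index)
    cols = [gene_index[g] for g in genes]
    r1 = np.corrcoef(expr.values[np.ix_(idx_a, cols)], rowvar=False)
    r2 = np.corrcoef(expr.values[np.ix_(idx_b, cols)], rowvar=False)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))

    def clamp(r: float) -> float:
        if abs(r) >= 1.0:
            logger.warning("|r| = 1 clamped before Fisher transform")
            return math.copysign(1.0 - 1e-12, r)
        return r

    rows = []
    for ia in range(len(genes)):
        for ib in range(ia + 1, len(genes)):
            ra, rb = clamp(float(r1[ia, ib])), clamp(float(r2[ia, ib]))
            z = (math.atanh(ra) - math.atanh(rb)) / se
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
            rows.append(
                CorrelationPairRow(
                    gene_a=genes[ia],
                    gene_b=genes[ib],
                    r_group1=ra,
                    r_group2=rb,
                    p_diff=max(p, np.finfo(float).tiny),
                )
            )
    rows.sort(key=lambda r: (-abs(r.r_group1), r.gene_a, r.gene_b))
    return rows[:top_k]


def write_results(rows: list, path) -> None:
    """Write result rows as a TSV with p-values at 4 significant digits."""

    def fmt(value) -> str:
        if isinstance(value, float):
            return "nan" if math.isnan(value) else f"{value:.4g}"
        return str(value)

    if rows and isinstance(rows[0], CorrelationPairRow):
        columns = ["gene_a", "gene_b", "r_group1", "r_group2", "p_diff"]
    else:
        columns = [
            "set_name",
            "size_declared",
            "size_used",
            "statistic",
            "p_raw",
            "p_adjusted",
            "tau",
            "stopped_early",
            "note",
        ]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(getattr(row, c)) for c in columns) + "\n")
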