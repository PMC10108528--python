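"""Linking TSS chromatin enrichment to gene expression.

Genes with a significantly enriched accessibility peak near their TSS are
classified against expression in the two compared cell types:

* ``congruent`` — the peak-enriched cell is also the significantly
  higher-expression cell (open chromatin with matching transcription).
* ``incongruent_repressed_in_a`` / ``_in_b`` — the chromatin is enriched in
  one cell while expression favors the other; the peak-enriched cell is
  "repressed" (open chromatin presumably held silent by repressors).
* ``unexpressed`` — both compared cells are at or below the expression floor.

Repressed genes are then tested for the stepwise "poised" pattern using
transcriptomes of transdifferentiated beta cells that retain an alpha or
delta lineage label: a poised beta-cell gene shows strictly increasing
expression origin < transdifferentiated < beta; a gene whose expression is
maximal in the transdifferentiated population is a transition gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .differential import DifferentialPeak
from .genes import Gene

DEFAULT_EXPRESSION_FLOOR = 0.0
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_MAX_Q = 0.05


@dataclass
class CongruenceCall:
    gene: str
    comparison: tuple[str, str]
    peak_enriched_in: str
    expression_higher_in: str | None
    klass: str  # congruent | incongruent_repressed_in_a | incongruent_repressed_in_b | unexpressed
    rpkm_a: float
    rpkm_b: float


@dataclass
class PoisedCall:
    gene: str
    origin_cell: str
    expr_origin: float
    expr_transdiff: float
    expr_beta: float
    pattern: str  # poised_beta_gene | transition_gene | other


def associate_tss_peaks(
    diff_peaks: list[DifferentialPeak],
    genes: list[Gene],
    window: int = 3000,
) -> tuple[dict[str, DifferentialPeak], dict[str, list[DifferentialPeak]]]:
    """Map genes to significant differential peaks whose midpoint is within
    ``window`` bp of the TSS.

    Returns (representative, audit): the representative peak per gene is the
    one with the smallest p-value (coordinate order breaks ties); the audit
    map retains every qualifying peak.
    """
    audit: dict[str, list[DifferentialPeak]] = {}
    for g in genes:
        hits = [
            p
            for p in diff_peaks
            if p.significant
            and p.region.chrom == g.chrom
            and abs(p.region.midpoint - g.tss) <= window
        ]
        if hits:
            hits.sort(key=lambda p: (p.p_value, p.region.start, p.region.end))
            audit[g.gene_id] = hits
    representative = {gid: hits[0] for gid, hits in audit.items()}
    return representative, audit


def classify_congruence(
    assoc: dict[str, DifferentialPeak],
    expr: pd.DataFrame,
    comparison: tuple[str, str],
    de: pd.DataFrame | None = None,
    floor: float = DEFAULT_EXPRESSION_FLOOR,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_q: float = DEFAULT_MAX_Q,
) -> tuple[list[CongruenceCall], pd.Series, int]:
    """Classify TSS-peak-bearing genes as congruent / incongruent / unexpressed.

    ``expr`` is an RPKM table indexed by gene with one column per cell type.
    ``de`` optionally carries the companion expression test (columns
    ``log2fc`` for cell_a vs cell_b and ``q_value``); when provided, the
    expression direction counts only if |log2fc| > min_abs_log2fc and
    q <= max_q. Without ``de``, any RPKM difference sets the direction.

    Returns (calls, class percentage summary, n_missing_expression).
    """
    cell_a, cell_b = comparison
    calls: list[CongruenceCall] = []
    n_missing = 0
    for gene, peak in sorted(assoc.items()):
        if gene not in expr.index:
            n_missing += 1
            continue
        ra, rb = float(expr.at[gene, cell_a]), float(expr.at[gene, cell_b])
        peak_cell = peak.enriched_in
        if peak_cell not in (cell_a, cell_b):
            raise ValueError(f"peak for {gene} enriched in {peak_cell!r}, not in the comparison")
        higher: str | None
        if de is not None and gene in de.index:
            lfc = float(de.at[gene, "log2fc"])
            q = float(de.at[gene, "q_value"])
            if abs(lfc) > min_abs_log2fc and q <= max_q:
                higher = cell_a if lfc > 0 else cell_b
            else:
                higher = None
        else:
            higher = cell_a if ra > rb else (cell_b if rb > ra else None)

        if ra <= floor and rb <= floor:
            klass = "unexpressed"
            higher = None
        elif higher is not None and higher == peak_cell:
            klass = "congruent"
        else:
            # chromatin open in peak_cell without an expression advantage there;
            # the lower-RPKM cell is called repressed (ties go to the peak cell,
            # which keeps the label invariant under swapping the comparison)
            repressed = peak_cell if ra == rb else (cell_a if ra < rb else cell_b)
            klass = (
                "incongruent_repressed_in_a" if repressed == cell_a else "incongruent_repressed_in_b"
            )
        calls.append(
            CongruenceCall(
                gene=gene,
                comparison=comparison,
                peak_enriched_in=peak_cell,
                expression_higher_in=higher,
                klass=klass,
                rpkm_a=ra,
                rpkm_b=rb,
            )
        )
    counts = pd.Series(0, index=[
        "congruent",
        "incongruent_repressed_in_a",
        "incongruent_repressed_in_b",
        "unexpressed",
    ], dtype=float)
    for c in calls:
        counts[c.klass] += 1
    summary = 100.0 * counts / counts.sum() if counts.sum() else counts
    return calls, summary, n_missing


def poised_stepwise_test(
    repressed_genes: list[str],
    expr: pd.DataFrame,
    origin_cell: str,
    transdiff_column: str | None = None,
    beta_column: str = "beta",
) -> tuple[list[PoisedCall], pd.Series]:
    """Test repressed genes for the stepwise poised pattern.

    ``poised_beta_gene`` requires strictly increasing expression
    origin < transdifferentiated < beta; ``transition_gene`` requires the
    transdifferentiated value to be the strict maximum; everything else
    (including ties) is ``other``. Returns (calls, fraction summary over the
    three patterns).
    """
    if transdiff_column is None:
        transdiff_column = f"{origin_cell}_transdiff"
    for col in (origin_cell, transdiff_column, beta_column):
        if col not in expr.columns:
            raise ValueError(f"expression table lacks required column {col!r}")
    calls: list[PoisedCall] = []
    for gene in repressed_genes:
        o = float(expr.at[gene, origin_cell])
        t = float(expr.at[gene, transdiff_column])
        b = float(expr.at[gene, beta_column])
        if o < t < b:
            pattern = "poised_beta_gene"
        elif t > o and t > b:
            pattern = "transition_gene"
        else:
            pattern = "other"
        calls.append(PoisedCall(gene, origin_cell, o, t, b, pattern))
    counts = pd.Series(0, index=["poised_beta_gene", "transition_gene", "other"], dtype=float)
    for c in calls:
        counts[c.pattern] += 1
    fractions = counts / counts.sum() if counts.sum() else counts
    return calls, fractions


def congruence_table(calls: list[CongruenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "comparison": [f"{c.comparison[0]}_vs_{c.comparison[1]}" for c in calls],
            "class": [c.klass for c in calls],
            "peak_enriched_in": [c.peak_enriched_in for c in calls],
            "expression_higher_in": [c.expression_higher_in or "" for c in calls],
            "rpkm_a": [c.rpkm_a for c in calls],
            "rpkm_b": [c.rpkm_b for c in calls],
        }
    )
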