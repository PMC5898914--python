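"""Per-dataset enrichment screens, gene-set intersection and over-representation.

Five published transcriptome datasets of fetal human neocortex are each
reduced to a gene set of progenitor-enriched genes by a declarative rule
(:class:`ScreenCriteria`): either a differential-expression threshold rule
(p-value cutoff, abundance floor, effect direction, optionally required
across all stages) or a correlation rule (positive correlation with
progenitor classes/zones, optional negative correlation with neurons,
optional detected-cell floor, optional requirement that the rule hold in
both samples of at least one stage pair).  Genes present in at least two of
the five sets form the progenitor-enriched catalogue; pairwise overlaps,
Venn partitions and term over-representation (hypergeometric upper tail
with Benjamini–Yekutieli adjustment) summarize the intersection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datasets_io import GeneSet


class ConfigurationError(ValueError):
    """The criteria reference columns or contrasts absent from the table."""


@dataclass(frozen=True)
class ScreenCriteria:
    """Declarative enrichment rule for one dataset.

    Threshold mode (``mode="threshold"``): a gene qualifies if, for at
    least one contrast in ``contrasts``, p < ``p_max`` and abundance >=
    ``min_abundance`` and the effect direction is positive, in every stage
    (``across_stages="all"``, the default) or any stage
    (``across_stages="any"``).

    Correlation mode (``mode="correlation"``): a gene qualifies if its
    correlation with at least one class in ``pos_targets`` exceeds
    ``pos_corr_min``, its correlation with ``neg_class`` (if set) is below
    ``neg_corr_max``, and it is detected in at least ``min_detected_cells``
    cells (if set).  When ``pairing`` lists sample pairs, the positive
    criterion must hold in both samples of at least one pair.
    """

    mode: str
    p_max: float = 0.01
    min_abundance: float = 0.0
    contrasts: tuple[str, ...] = ()
    across_stages: str = "all"
    pos_targets: tuple[str, ...] = ()
    pos_corr_min: float = 0.0
    neg_class: str | None = None
    neg_corr_max: float = 0.0
    min_detected_cells: int | None = None
    pairing: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "correlation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "threshold":
            if not (0.0 < self.p_max <= 1.0):
                raise ValueError("p_max must lie in (0, 1]")
            if self.min_abundance < 0:
                raise ValueError("min_abundance must be >= 0")
            if self.across_stages not in ("all", "any"):
                raise ValueError("across_stages must be 'all' or 'any'")


#: the five screening rules as stated by the study's methods
PUBLISHED_CRITERIA: dict[str, ScreenCriteria] = {
    # germinal zones (VZ/iSVZ/oSVZ) vs cortical plate, across all stages
    "Fietz": ScreenCriteria(
        mode="threshold",
        p_max=0.01,
        min_abundance=1.5,
        contrasts=("VZ_vs_CP", "iSVZ_vs_CP", "oSVZ_vs_CP"),
        across_stages="all",
    ),
    # aRG or bRG (S-G2-M) vs neuron-enriched fraction
    "Florio": ScreenCriteria(
        mode="threshold",
        p_max=0.01,
        min_abundance=0.5,
        contrasts=("aRG_vs_N", "bRG_vs_N"),
        across_stages="all",
    ),
    # aRG and/or bRG vs intermediate-progenitor/neuron population
    "Johnson": ScreenCriteria(
        mode="threshold",
        p_max=0.01,
        min_abundance=0.1,
        contrasts=("aRG_vs_IPN", "bRG_vs_IPN"),
        across_stages="all",
    ),
    # laminar correlation with a germinal zone, in both samples of a stage pair
    "Miller": ScreenCriteria(
        mode="correlation",
        pos_targets=("VZ", "iSVZ", "oSVZ"),
        pos_corr_min=0.25,
        pairing=(("wpc15_a", "wpc15_b"), ("wpc21_a", "wpc21_b")),
    ),
    # single-cell correlation with radial glia or bIPs, anti-correlated with N
    "Pollen": ScreenCriteria(
        mode="correlation",
        pos_targets=("RG", "bIP"),
        pos_corr_min=0.1,
        neg_class="N",
        neg_corr_max=0.03,
        min_detected_cells=9,
    ),
}


def apply_threshold_screen(
    table: pd.DataFrame, criteria: ScreenCriteria, name: str = "screen"
) -> GeneSet:
    """Apply a differential-expression threshold rule.

    ``table`` is long format with columns ``gene_id``, ``contrast``,
    ``stage``, ``p_value``, ``abundance`` and optionally ``log2fc``.  The
    effect direction is taken from the sign of ``log2fc`` when that column
    is present, otherwise every row is assumed to be oriented
    progenitor-over-reference.  Comparisons are strict exactly as printed:
    ``p < p_max`` and ``abundance >= min_abundance``.
    """
    if criteria.mode != "threshold":
        raise ConfigurationError("criteria mode must be 'threshold'")
    required = {"gene_id", "contrast", "stage", "p_value", "abundance"}
    if not required <= set(table.columns):
        raise ConfigurationError(f"table lacks columns {sorted(required - set(table.columns))}")
    present = set(table["contrast"].unique())
    absent = set(criteria.contrasts) - present
    if absent:
        raise ConfigurationError(f"contrasts {sorted(absent)} absent from table")
    df = table[table["contrast"].isin(criteria.contrasts)].copy()
    ok = (df["p_value"] < criteria.p_max) & (df["abundance"] >= criteria.min_abundance)
    if "log2fc" in df.columns:
        ok &= df["log2fc"] > 0
    df["ok"] = ok
    agg = "all" if criteria.across_stages == "all" else "any"
    per_contrast = df.groupby(["gene_id", "contrast"])["ok"].agg(agg)
    per_gene = per_contrast.groupby("gene_id").any()
    return GeneSet(name=name, members=frozenset(per_gene[per_gene].index))


def apply_correlation_screen(
    table: pd.DataFrame, criteria: ScreenCriteria, name: str = "screen"
) -> GeneSet:
    """Apply a correlation rule.

    ``table`` is long format with columns ``gene_id``, ``label``,
    ``sample``, ``correlation`` and optionally ``detected_cells`` (constant
    per gene).  Comparisons are strict: positive correlation must exceed
    ``pos_corr_min`` and the excluded-class correlation must be below
    ``neg_corr_max``.
    """
    if criteria.mode != "correlation":
        raise ConfigurationError("criteria mode must be 'correlation'")
    required = {"gene_id", "label", "sample", "correlation"}
    if not required <= set(table.columns):
        raise ConfigurationError(f"table lacks columns {sorted(required - set(table.columns))}")
    labels = set(table["label"].unique())
    missing = set(criteria.pos_targets) - labels
    if criteria.neg_class is not None and criteria.neg_class not in labels:
        missing.add(criteria.neg_class)
    if missing:
        raise ConfigurationError(f"correlation labels {sorted(missing)} absent from table")

    samples = set(table["sample"].unique())
    pos = table[table["label"].isin(criteria.pos_targets)]
    pos_hit = pos[pos["correlation"] > criteria.pos_corr_min]
    # per (gene, sample): does any positive target clear the bar
    hit_by_sample = (
        pos_hit.groupby(["gene_id", "sample"]).size().unstack(fill_value=0) > 0
    ).reindex(columns=sorted(samples), fill_value=False)

    genes = pd.Index(sorted(table["gene_id"].unique()))
    if criteria.pairing:
        keep = pd.Series(False, index=genes)
        for a, b in criteria.pairing:
            if a not in samples or b not in samples:
                raise ConfigurationError(f"pairing samples {(a, b)} absent from table")
            both = (hit_by_sample[a] & hit_by_sample[b]).reindex(genes, fill_value=False)
            keep |= both
    else:
        keep = hit_by_sample.any(axis=1).reindex(genes, fill_value=False)

    if criteria.neg_class is not None:
        neg = table[table["label"] == criteria.neg_class]
        neg_ok = (
            neg.groupby("gene_id")["correlation"]
            .max()
            .lt(criteria.neg_corr_max)
            .reindex(genes, fill_value=False)
        )
        keep &= neg_ok
    if criteria.min_detected_cells is not None:
        if "detected_cells" not in table.columns:
            raise ConfigurationError("criteria require a detected_cells column")
        cells = table.groupby("gene_id")["detected_cells"].first()
        keep &= cells.ge(criteria.min_detected_cells).reindex(genes, fill_value=False)
    return GeneSet(name=name, members=frozenset(keep[keep].index))


def build_support_table(sets: Sequence[GeneSet], min_sets: int = 2) -> pd.DataFrame:
    """Per-gene dataset membership, support count and enrichment flag.

    A gene is flagged enriched when it appears in at least ``min_sets`` of
    the input sets (the study's at-least-two-of-five rule).
    """
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate dataset names")
    if not 1 <= min_sets <= len(sets):
        raise ValueError("min_sets out of range")
    union = sorted(set().union(*(s.members for s in sets)))
    data = {s.name: [g in s.members for g in union] for s in sets}
    table = pd.DataFrame(data, index=pd.Index(union, name="gene_id"))
    table["support"] = table[names].sum(axis=1)
    table["combination"] = table[names].apply(
        lambda row: "+".join(sorted(n for n in names if row[n])), axis=1
    )
    table["enriched"] = table["support"] >= min_sets
    return table


def venn_partition(
    sets: Sequence[GeneSet], by_cardinality: bool = False
) -> dict:
    """Exclusive-region counts of the Venn diagram over ``sets``.

    Returns a mapping from each non-empty dataset combination (a frozenset
    of names; 2^n - 1 regions) to the number of genes found in exactly
    those sets.  With ``by_cardinality=True``, regions are grouped and
    summed by combination size instead.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate dataset names")
    regions: dict[frozenset, int] = {}
    for k in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), k):
            inside = frozenset.intersection(*(sets[i].members for i in combo))
            outside = set().union(
                *(sets[i].members for i in range(len(sets)) if i not in combo)
            ) if len(combo) < len(sets) else set()
            regions[frozenset(names[i] for i in combo)] = len(inside - outside)
    if by_cardinality:
        grouped: dict[int, int] = {}
        for combo, count in regions.items():
            grouped[len(combo)] = grouped.get(len(combo), 0) + count
        return grouped
    return regions


def overlap_matrix(sets: Sequence[GeneSet], metric: str = "over_min") -> pd.DataFrame:
    """Symmetric pairwise overlap fractions between gene sets.

    Metrics: ``over_min`` = |A∩B| / min(|A|,|B|) (default), ``jaccard`` =
    |A∩B| / |A∪B|, ``over_mean`` = |A∩B| / mean(|A|,|B|).
    """
    if metric not in ("over_min", "jaccard", "over_mean"):
        raise ValueError(f"unknown metric {metric!r}")
    names = [s.name for s in sets]
    n = len(sets)
    mat = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = sets[i].members, sets[j].members
        inter = len(a & b)
        if metric == "over_min":
            denom = min(len(a), len(b))
            if denom == 0:
                raise ValueError("over_min undefined for an empty set")
        elif metric == "jaccard":
            denom = len(a | b)
            denom = denom if denom else 1
        else:
            denom = (len(a) + len(b)) / 2
            denom = denom if denom else 1
        mat[i, j] = mat[j, i] = inter / denom
    return pd.DataFrame(mat, index=names, columns=names)


def benjamini_yekutieli(p: Sequence[float]) -> np.ndarray:
    """BY-adjusted p-values (FDR control under arbitrary dependence)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def enrichment_test(
    query: GeneSet,
    universe: GeneSet,
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation of ``query`` within ``universe``.

    For each term the p-value is the hypergeometric upper-tail probability
    of drawing at least the observed overlap when sampling ``len(query)``
    genes from the universe; adjustment is Benjamini–Yekutieli across all
    tested terms, with significance at adjusted p < ``alpha``.
    """
    if not query.members <= universe.members:
        raise ValueError("query is not a subset of the universe")
    rows = []
    m = len(universe.members)
    n_query = len(query.members)
    for term, genes in annotation.items():
        genes = set(genes) & universe.members
        stray = set(annotation[term]) - universe.members
        if stray:
            raise ValueError(f"term {term!r} annotates genes outside the universe")
        k = len(genes & query.members)
        # P(X >= k) for X ~ Hypergeom(M=m, K=len(genes), N=n_query)
        p = float(hypergeom.sf(k - 1, m, len(genes), n_query))
        rows.append((term, len(genes), k, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
    table["p_adjusted"] = benjamini_yekutieli(table["p_value"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    return table.sort_values("p_value", ignore_index=True)
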