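"""Seeded generators for every input the pipeline consumes, with planted truth.

The study's raw datasets are not redistributable, so each pipeline stage is
exercised on synthetic inputs that emulate the *summary-level* statistical
structure the real pipeline consumed: five per-dataset summary tables with
planted enriched genes that clear the published thresholds with margin and
background genes that straddle them on the failing side; ancestral/derived
mRNA pairs of controllable divergence with repeat-free construction;
error-free fixed-length reads with recorded source; ortholog sets with a
gene birth planted on a tree node and inherited loss events on descendant
branches; and qPCR Ct tables derived from integer copy numbers with
controllable Gaussian noise.  Every generator is byte-deterministic under
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .copy_number import CtTable
from .orf_evolution import STOP_CODONS, SpeciesTree
from .paralog_expression import ParalogGroup
from .screen import PUBLISHED_CRITERIA, ScreenCriteria

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs shared by the generators; defaults mirror the study conditions.

    ``planted_margin`` is the fractional clearance by which planted genes
    beat each screen threshold (0.5 = p-values at most half the cutoff,
    abundances at least 1.5x the floor, and so on).
    """

    seed: int = 0
    # screen tables
    n_genes: int = 200
    n_planted: int = 20
    planted_min_sets: int = 2
    planted_margin: float = 0.5
    # paralog pairs and reads
    seq_length: int = 600
    n_snps: int = 6
    n_indels: int = 2
    indel_max_len: int = 3
    read_length: int = 50
    n_reads: int = 2000
    # ortholog sets
    n_codons: int = 100
    # Ct tables
    n_replicates: int = 3
    ct_noise_sd: float = 0.05
    base_ct: float = 24.0
    species_offset_sd: float = 0.3
    efficiency: float = 2.0
    ref_gene: str = "STX12"
    ref_species: str = "bonobo"

    def __post_init__(self) -> None:
        if not (0.0 < self.planted_margin < 1.0):
            raise ValueError("planted_margin must lie in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# screen summary tables
# ---------------------------------------------------------------------------

#: stages/samples of each emulated dataset
_DATASET_STAGES = {
    "Fietz": ("wpc13", "wpc14", "wpc15", "wpc16"),
    "Florio": ("wpc13",),
    "Johnson": ("wpc18",),
}
_MILLER_SAMPLES = ("wpc15_a", "wpc15_b", "wpc21_a", "wpc21_b")
_POLLEN_LABELS = ("RG", "bIP", "N")


def _planted_threshold_rows(rng, gene, crit: ScreenCriteria, stages, margin):
    rows = []
    for contrast in crit.contrasts:
        for stage in stages:
            rows.append(
                {
                    "gene_id": gene,
                    "contrast": contrast,
                    "stage": stage,
                    "p_value": float(rng.uniform(0, crit.p_max * (1 - margin))),
                    "abundance": float(
                        crit.min_abundance * (1 + margin) + rng.uniform(0, 2)
                    ),
                    "log2fc": float(rng.uniform(0.5, 3.0)),
                }
            )
    return rows


def _background_threshold_rows(rng, gene, crit: ScreenCriteria, stages, margin):
    """Rows that straddle the thresholds but fail every contrast."""
    mode = rng.choice(["p", "abundance", "stage"] if len(stages) > 1 else ["p", "abundance"])
    rows = []
    for contrast in crit.contrasts:
        fail_stage = stages[int(rng.integers(len(stages)))]
        for stage in stages:
            p = float(rng.uniform(0, crit.p_max * (1 - margin)))
            ab = float(crit.min_abundance * (1 + margin) + rng.uniform(0, 2))
            fc = float(rng.uniform(0.5, 3.0))
            if mode == "p":
                p = float(rng.uniform(crit.p_max, min(1.0, crit.p_max * 5)))
            elif mode == "abundance":
                ab = float(rng.uniform(0, crit.min_abundance * 0.999))
            elif stage == fail_stage:
                p = float(rng.uniform(crit.p_max, min(1.0, crit.p_max * 5)))
            rows.append(
                {
                    "gene_id": gene,
                    "contrast": contrast,
                    "stage": stage,
                    "p_value": p,
                    "abundance": ab,
                    "log2fc": fc,
                }
            )
    return rows


def _miller_rows(rng, gene, crit: ScreenCriteria, planted, margin):
    rows = []
    if planted:
        zone = crit.pos_targets[int(rng.integers(len(crit.pos_targets)))]
        pair = _MILLER_SAMPLES[:2] if rng.random() < 0.5 else _MILLER_SAMPLES[2:]
        for sample in _MILLER_SAMPLES:
            for z in crit.pos_targets:
                if z == zone and sample in pair:
                    corr = float(crit.pos_corr_min + margin * (1 - crit.pos_corr_min) * rng.uniform(0.5, 1.0))
                else:
                    corr = float(rng.uniform(-0.5, crit.pos_corr_min * 0.9))
                rows.append(
                    {"gene_id": gene, "label": z, "sample": sample, "correlation": corr}
                )
        return rows
    mode = rng.choice(["low", "unpaired"])
    for pair in (_MILLER_SAMPLES[:2], _MILLER_SAMPLES[2:]):
        lucky = pair[int(rng.integers(2))]  # at most one sample per pair passes
        for sample in pair:
            for z in crit.pos_targets:
                if mode == "unpaired" and sample == lucky and z == crit.pos_targets[0]:
                    corr = float(crit.pos_corr_min + 0.2 * rng.uniform(0.5, 1.0))
                else:
                    corr = float(rng.uniform(-0.5, crit.pos_corr_min * 0.95))
                rows.append(
                    {"gene_id": gene, "label": z, "sample": sample, "correlation": corr}
                )
    return rows


def _pollen_rows(rng, gene, crit: ScreenCriteria, planted, margin):
    rows = []
    floor = crit.min_detected_cells or 0
    if planted:
        target = crit.pos_targets[int(rng.integers(len(crit.pos_targets)))]
        cells = int(floor + rng.integers(5, 50))
        for label in _POLLEN_LABELS:
            if label == target:
                corr = float(crit.pos_corr_min + margin * (1 - crit.pos_corr_min) * rng.uniform(0.5, 1.0))
            elif label == crit.neg_class:
                corr = float(rng.uniform(-0.6, crit.neg_corr_max - margin * 0.2))
            else:
                corr = float(rng.uniform(-0.3, 0.3))
            rows.append(
                {
                    "gene_id": gene,
                    "label": label,
                    "sample": "sc",
                    "correlation": corr,
                    "detected_cells": cells,
                }
            )
        return rows
    mode = rng.choice(["low_pos", "high_neg", "few_cells"])
    cells = int(rng.integers(0, floor)) if mode == "few_cells" else int(floor + rng.integers(0, 50))
    for label in _POLLEN_LABELS:
        if label == crit.neg_class:
            if mode == "high_neg":
                corr = float(rng.uniform(crit.neg_corr_max, 0.5))
            else:
                corr = float(rng.uniform(-0.6, crit.neg_corr_max * 0.5))
        else:
            if mode == "low_pos":
                corr = float(rng.uniform(-0.5, crit.pos_corr_min * 0.95))
            else:
                corr = float(rng.uniform(crit.pos_corr_min, 0.9)) if mode != "low_pos" else 0.0
        rows.append(
            {
                "gene_id": gene,
                "label": label,
                "sample": "sc",
                "correlation": corr,
                "detected_cells": cells,
            }
        )
    return rows


def gen_screen_tables(
    config: GeneratorConfig,
    criteria: Mapping[str, ScreenCriteria] | None = None,
    planted_n_datasets: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Five summary tables with planted enriched genes, plus the truth table.

    Planted genes clear the thresholds of ``planted_min_sets`` (or exactly
    ``planted_n_datasets``) randomly chosen datasets with margin and fail
    everywhere else; background genes fail every dataset with values that
    straddle the thresholds.  Returns ``(tables, truth)`` where truth has
    columns ``gene_id``, ``planted`` and ``planted_datasets``.
    """
    criteria = dict(criteria or PUBLISHED_CRITERIA)
    rng = config.rng()
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    planted = set(genes[: config.n_planted])
    margin = config.planted_margin
    names = sorted(criteria)
    membership: dict[str, set[str]] = {}
    for gene in genes:
        if gene in planted:
            k = planted_n_datasets or int(
                rng.integers(config.planted_min_sets, len(names) + 1)
            )
            membership[gene] = set(rng.choice(names, size=k, replace=False))
        else:
            membership[gene] = set()

    tables: dict[str, pd.DataFrame] = {}
    for name in names:
        crit = criteria[name]
        rows: list[dict] = []
        for gene in genes:
            is_in = name in membership[gene]
            if crit.mode == "threshold":
                stages = _DATASET_STAGES.get(name, ("s1",))
                if is_in:
                    rows += _planted_threshold_rows(rng, gene, crit, stages, margin)
                else:
                    rows += _background_threshold_rows(rng, gene, crit, stages, margin)
            elif name == "Miller" or (crit.pairing and crit.neg_class is None):
                rows += _miller_rows(rng, gene, crit, is_in, margin)
            else:
                rows += _pollen_rows(rng, gene, crit, is_in, margin)
        tables[name] = pd.DataFrame(rows)

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "planted": [g in planted for g in genes],
            "planted_datasets": [",".join(sorted(membership[g])) for g in genes],
        }
    )
    return tables, truth


# ---------------------------------------------------------------------------
# paralog pairs and reads
# ---------------------------------------------------------------------------


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _repeat_free(seq: str, window: int) -> bool:
    if len(seq) <= window:
        return True
    windows = [seq[i : i + window] for i in range(len(seq) - window + 1)]
    return len(set(windows)) == len(windows)


def gen_paralog_pair(
    config: GeneratorConfig,
    ancestral_id: str = "ANC",
    derived_id: str = "DER",
) -> tuple[ParalogGroup, pd.DataFrame]:
    """An ancestral mRNA and a derived copy with planted divergence.

    The derived sequence carries exactly ``n_snps`` substitutions and
    ``n_indels`` indels (1..``indel_max_len`` nt, insertions or deletions)
    at recorded ancestral positions, spaced so that each edit yields one
    diagnostic site.  Both sequences are free of internal repeats of
    ``read_length`` so unique-occurrence classification is well posed.
    Returns the pair and a truth table (kind, ancestral position, alleles).
    """
    rng = config.rng()
    n_sites = config.n_snps + config.n_indels
    spacing = config.indel_max_len + 4
    lo, hi = config.read_length, config.seq_length - config.read_length
    if n_sites and (hi <= lo or (hi - lo) // spacing < n_sites):
        raise ValueError("requested diagnostic-site density is infeasible")
    for _ in range(50):
        anc = _random_seq(rng, config.seq_length)
        if not _repeat_free(anc, config.read_length):
            continue
        if n_sites:
            offsets = rng.choice((hi - lo) // spacing, size=n_sites, replace=False)
            positions = sorted(lo + int(o) * spacing for o in offsets)
        else:
            positions = []
        kinds = ["SNP"] * config.n_snps + ["indel"] * config.n_indels
        rng.shuffle(kinds)
        edits = list(zip(positions, kinds))
        derived = anc
        truth_rows = []
        for pos, kind in sorted(edits, reverse=True):
            if kind == "SNP":
                old = derived[pos]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                derived = derived[:pos] + new + derived[pos + 1 :]
                truth_rows.append(
                    {"kind": "SNP", "ancestral_pos": pos, "ancestral_allele": old, "derived_allele": new}
                )
            else:
                k = int(rng.integers(1, config.indel_max_len + 1))
                if rng.random() < 0.5:  # deletion in derived
                    truth_rows.append(
                        {
                            "kind": "indel",
                            "ancestral_pos": pos,
                            "ancestral_allele": derived[pos : pos + k],
                            "derived_allele": "-",
                        }
                    )
                    derived = derived[:pos] + derived[pos + k :]
                else:  # insertion in derived
                    ins = _random_seq(rng, k)
                    derived = derived[:pos] + ins + derived[pos:]
                    truth_rows.append(
                        {
                            "kind": "indel",
                            "ancestral_pos": pos,
                            "ancestral_allele": "-",
                            "derived_allele": ins,
                        }
                    )
        if not _repeat_free(derived, config.read_length):
            continue
        truth = pd.DataFrame(
            sorted(truth_rows, key=lambda r: r["ancestral_pos"]),
            columns=["kind", "ancestral_pos", "ancestral_allele", "derived_allele"],
        )
        group = ParalogGroup(
            ancestral_id=ancestral_id,
            derived_id=derived_id,
            ancestral_seq=anc,
            derived_seq=derived,
        )
        return group, truth
    raise RuntimeError("failed to construct a repeat-free paralog pair")


def gen_reads(
    pair: ParalogGroup,
    proportions: tuple[float, float],
    config: GeneratorConfig,
) -> tuple[list[str], pd.DataFrame]:
    """Error-free fixed-length reads drawn uniformly from the paralog pair.

    ``proportions`` are the (ancestral, derived) mixture weights.  Returns
    the reads and a truth table with each read's source paralog and start
    position.
    """
    if config.read_length > min(len(pair.ancestral_seq), len(pair.derived_seq)):
        raise ValueError("read length exceeds sequence length")
    total = sum(proportions)
    if total <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = [p / total for p in proportions]
    rng = config.rng()
    sources = rng.choice([0, 1], size=config.n_reads, p=weights)
    reads: list[str] = []
    rows = []
    seqs = (pair.ancestral_seq, pair.derived_seq)
    ids = (pair.ancestral_id, pair.derived_id)
    for src in sources:
        seq = seqs[src]
        start = int(rng.integers(0, len(seq) - config.read_length + 1))
        reads.append(seq[start : start + config.read_length])
        rows.append({"source": ids[src], "start": start})
    truth = pd.DataFrame(rows, columns=["source", "start"])
    return reads, truth


# ---------------------------------------------------------------------------
# ortholog sets on a tree
# ---------------------------------------------------------------------------


def _random_cds(rng, n_codons: int) -> str:
    codons = ["ATG"]
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    idx = rng.integers(0, len(sense), size=n_codons - 2)
    codons += [sense[i] for i in idx]
    codons.append("TAA")
    return "".join(codons)


def simulate_edge_losses(
    tree: SpeciesTree,
    origin: str,
    loss_prob: float,
    rng: np.random.Generator,
    human_leaf: str = "human",
) -> dict[str, bool]:
    """Per-species broken/intact pattern from inherited branch losses.

    On every branch below the origin node an independent gene-death event
    fires with probability ``loss_prob`` and is inherited by all
    descendants.  Branches on the path to the human leaf never lose the
    gene (the catalogue conditions on an intact human ortholog).
    """
    node = tree.clade_node(origin)
    human_path: set[int] = set()
    leaf = tree.clade_node("Homo") if human_leaf == "human" else None
    cur = leaf
    while cur is not None:
        human_path.add(id(cur))
        cur = cur.parent_node
    broken: dict[str, bool] = {}

    def walk(n, lost: bool) -> None:
        if n is not node:
            if not lost and id(n) not in human_path:
                lost = bool(rng.random() < loss_prob)
        if n.is_leaf():
            broken[n.taxon.label] = lost
            return
        for child in n.child_nodes():
            walk(child, lost)

    walk(node, False)
    return broken


def gen_ortholog_set(
    tree: SpeciesTree,
    origin: str,
    loss_prob: float,
    config: GeneratorConfig,
) -> tuple[str, dict[str, str], pd.DataFrame]:
    """Aligned orthologs of a gene born on ``origin`` with branch losses.

    Returns ``(reference_cds, alignments, truth)``: the human reference
    CDS, per-species gapped sequences aligned to it (species outside the
    origin clade are absent), and a truth table with each species' planted
    status (intact / frameshift / premature_stop / absent) and event
    position.  Broken species carry either a 1-bp deletion (frameshift) or
    a stop-codon substitution at a random internal codon.
    """
    if origin not in tree.clade_labels:
        raise ValueError(f"unknown origin clade {origin!r}")
    rng = config.rng()
    ref = _random_cds(rng, config.n_codons)
    inside = tree.leaves(origin)
    broken = simulate_edge_losses(tree, origin, loss_prob, rng)
    alignments: dict[str, str] = {}
    rows = []
    for species in sorted(tree.species()):
        if species not in inside:
            rows.append({"species": species, "status": "absent", "event_pos": -1})
            continue
        if not broken[species]:
            alignments[species] = ref
            rows.append({"species": species, "status": "intact", "event_pos": -1})
            continue
        codon = int(rng.integers(1, config.n_codons - 1))
        if rng.random() < 0.5:  # 1-bp deletion -> frameshift
            pos = 3 * codon + int(rng.integers(0, 3))
            alignments[species] = ref[:pos] + "-" + ref[pos + 1 :]
            rows.append({"species": species, "status": "frameshift", "event_pos": pos})
        else:  # premature stop
            alignments[species] = ref[: 3 * codon] + "TAG" + ref[3 * codon + 3 :]
            rows.append(
                {"species": species, "status": "premature_stop", "event_pos": codon}
            )
    truth = pd.DataFrame(rows, columns=["species", "status", "event_pos"])
    return ref, alignments, truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def gen_ct_table(
    copy_numbers: Mapping[str, Mapping[str, int]] | Mapping[str, int],
    config: GeneratorConfig,
) -> tuple[CtTable, pd.DataFrame]:
    """A qPCR Ct table realizing the given integer copy-number truth.

    ``copy_numbers`` maps gene group -> species -> copies (or species ->
    copies for a single unnamed target).  Each measurement is
    ``base - log_E(copies) + species offset + N(0, ct_noise_sd)``; the
    species offset (template amount variation) is shared by the target and
    the single-copy normalizer, as in a real ΔΔCt design.
    """
    first = next(iter(copy_numbers.values()))
    if not isinstance(first, Mapping):
        copy_numbers = {"target": dict(copy_numbers)}  # type: ignore[dict-item]
    for target, per_species in copy_numbers.items():
        for species, copies in per_species.items():
            if copies <= 0:
                raise ValueError(f"{target}/{species}: copies must be positive")
    rng = config.rng()
    species = sorted({s for per in copy_numbers.values() for s in per})
    offsets = {s: float(rng.normal(0, config.species_offset_sd)) for s in species}
    log_e = np.log(config.efficiency)
    rows = []
    groups = {config.ref_gene: {s: 1 for s in species}, **copy_numbers}
    for target, per_species in groups.items():
        base = config.base_ct + float(rng.uniform(-2, 2))
        for s in species:
            copies = per_species[s]
            mean_ct = base - np.log(copies) / log_e + offsets[s]
            for rep in range(1, config.n_replicates + 1):
                ct = mean_ct + float(rng.normal(0, config.ct_noise_sd)) if config.ct_noise_sd > 0 else mean_ct
                rows.append(
                    {"gene_group": target, "species": s, "replicate": rep, "ct": float(ct)}
                )
    data = pd.DataFrame(rows)
    table = CtTable(
        data=data,
        ref_gene=config.ref_gene,
        ref_species=config.ref_species,
        efficiency=config.efficiency,
    )
    truth_rows = [
        {"gene_group": t, "species": s, "copies": c}
        for t, per in copy_numbers.items()
        for s, c in per.items()
    ]
    return table, pd.DataFrame(truth_rows, columns=["gene_group", "species", "copies"])
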