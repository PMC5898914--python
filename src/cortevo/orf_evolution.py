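"""ORF intactness of orthologs, gene dating on a primate tree, branch birth rates.

A gene's origin is assigned to the most recent common ancestor of the
species in which its reading frame is intact.  Intactness is scored from a
gapped pairwise alignment of the ortholog against a reference (human)
coding sequence: indels are processed left-to-right with a cumulative
reading-frame phase, a stop codon encountered while the phase is shifted
(or a shift never compensated) is a frameshift, and an in-frame stop before
the reference's terminal codon is a premature stop.  Broken descendants
inside the origin clade do not pull the assignment tipward.  Per-branch
gene-birth counts are related to neutral branch lengths with an exact
Poisson upper-tail outlier test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from scipy.stats import poisson

from .datasets_io import CLADE_LABELS

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

VERDICTS = ("intact", "frameshift", "premature_stop", "missing")


class OrfInputError(ValueError):
    """The reference CDS violates the scanner's preconditions."""


@dataclass(frozen=True)
class OrfEvent:
    kind: str  # "frameshift" | "premature_stop"
    position: int  # codon index for stops, ortholog nt position for frameshifts


@dataclass(frozen=True)
class OrfStatus:
    """Reading-frame verdict for one species' ortholog."""

    verdict: str
    events: tuple[OrfEvent, ...] = ()
    predicted_protein_length: int = 0

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "intact" and self.events:
            raise ValueError("intact status cannot carry events")
        if self.predicted_protein_length < 0:
            raise ValueError("protein length must be >= 0")

    @property
    def intact(self) -> bool:
        return self.verdict == "intact"


@dataclass(frozen=True)
class CladeAssignment:
    gene_id: str
    origin: str
    statuses: Mapping[str, OrfStatus] = field(default_factory=dict)


class SpeciesTree:
    """Rooted primate tree with labeled clade nodes and neutral branch lengths.

    The eight nested clade labels on the path from the human leaf to the
    root (Homo ... Haplorrhini) name the branches on which progenitor-
    enriched genes can arise; "Homo" denotes the terminal branch to the
    human leaf.
    """

    def __init__(self, tree: dendropy.Tree, human_leaf: str = "human") -> None:
        self._tree = tree
        self._human_leaf = human_leaf
        self._nodes: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.is_leaf() and node.taxon else node.label
            if label:
                if label in self._nodes:
                    raise ValueError(f"duplicate node label {label!r}")
                self._nodes[label] = node
        if human_leaf not in self._nodes:
            raise ValueError(f"tree lacks a {human_leaf!r} leaf")
        # clade label -> node (Homo is the human leaf itself)
        self._clades: dict[str, dendropy.Node] = {}
        for label in CLADE_LABELS:
            node = self._nodes.get(human_leaf if label == "Homo" else label)
            if node is not None:
                self._clades[label] = node
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and (node.edge.length or 0) <= 0:
                raise ValueError("all branch lengths must be > 0")

    @classmethod
    def from_newick(cls, source: str | Path, **kwargs) -> "SpeciesTree":
        path = Path(source)
        tree = dendropy.Tree.get(
            data=path.read_text() if path.exists() else str(source),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tree.is_rooted = True
        return cls(tree, **kwargs)

    @property
    def clade_labels(self) -> tuple[str, ...]:
        return tuple(label for label in CLADE_LABELS if label in self._clades)

    def clade_node(self, label: str) -> dendropy.Node:
        return self._clades[label]

    def branch_length(self, label: str) -> float:
        return float(self._clades[label].edge.length)

    def leaves(self, label: str) -> frozenset[str]:
        """Leaf species contained in a clade."""
        node = self._clades[label]
        if node.is_leaf():
            return frozenset([node.taxon.label])
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def species(self) -> frozenset[str]:
        return frozenset(l.taxon.label for l in self._tree.leaf_node_iter())

    def mrca_clade(self, species: Iterable[str]) -> str:
        """Smallest labeled clade containing all given species.

        The MRCA node of the species is located, then walked rootward to
        the nearest node carrying one of the recognised clade labels.
        """
        species = list(species)
        if not species:
            raise ValueError("no species given")
        unknown = set(species) - self.species()
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        if len(species) == 1:
            node = self._nodes[species[0]]
        else:
            node = self._tree.mrca(taxon_labels=species)
        label_of = {id(n): lab for lab, n in self._clades.items()}
        while node is not None:
            if id(node) in label_of:
                return label_of[id(node)]
            node = node.parent_node
        raise ValueError(
            f"MRCA of {sorted(species)} lies outside the labeled clades"
        )

    def path_to_root(self, label: str) -> list[str]:
        """Clade labels from ``label`` rootward (inclusive)."""
        idx = CLADE_LABELS.index(label)
        return [l for l in CLADE_LABELS[idx:] if l in self._clades]


def _validate_reference(ref: str) -> None:
    if len(ref) == 0 or len(ref) % 3 != 0:
        raise OrfInputError("reference CDS length must be a positive multiple of 3")
    if ref[:3] != START_CODON:
        raise OrfInputError("reference CDS must start with ATG")
    if ref[-3:] not in STOP_CODONS:
        raise OrfInputError("reference CDS must end with a stop codon")
    if set(ref) - set("ACGT"):
        raise OrfInputError("reference CDS must be plain ACGT")


def scan_orf(reference_cds: str, ortholog: str) -> OrfStatus:
    """Score an ortholog's reading frame against an aligned reference CDS.

    Parameters
    ----------
    reference_cds
        The reference coding sequence, possibly gapped; ungapped it must
        start with ATG, end with a stop codon and have length divisible
        by 3.
    ortholog
        The orthologous sequence aligned to the reference (same gapped
        length).
    """
    ref_aln = reference_cds.upper()
    orth_aln = ortholog.upper()
    if len(ref_aln) != len(orth_aln):
        raise OrfInputError("reference and ortholog alignments differ in length")
    ref = ref_aln.replace("-", "")
    _validate_reference(ref)
    orth = orth_aln.replace("-", "")
    if not orth:
        return OrfStatus(verdict="missing")

    # For every ortholog position, the cumulative frame shift (inserted
    # minus deleted bases so far, mod 3) and the reference coordinate of
    # the column it sits in (previous reference base for insertions).
    shift_at: list[int] = []
    ref_coord_at: list[int] = []
    shift_start: list[int] = []  # orth pos where the current nonzero stretch began
    shift = 0
    stretch_start = -1
    ref_pos = -1
    for col in range(len(ref_aln)):
        r, o = ref_aln[col], orth_aln[col]
        if r != "-":
            ref_pos += 1
        if o == "-":
            if r == "-":
                continue
            prev = shift
            shift = (shift - 1) % 3
            if prev == 0 and shift != 0:
                stretch_start = len(shift_at)
            continue
        if r == "-":
            prev = shift
            shift = (shift + 1) % 3
            if prev == 0 and shift != 0:
                stretch_start = len(shift_at)
        shift_at.append(shift)
        ref_coord_at.append(ref_pos)
        shift_start.append(stretch_start)

    # translate the ortholog codon by codon from its own start
    first_stop_codon = None
    for i in range(len(orth) // 3):
        if orth[3 * i : 3 * i + 3] in STOP_CODONS:
            first_stop_codon = i
            break
    protein_length = first_stop_codon if first_stop_codon is not None else len(orth) // 3

    terminal_start = len(ref) - 3  # reference coordinate of the terminal stop

    if first_stop_codon is not None:
        pos = 3 * first_stop_codon
        stop_shift = shift_at[pos]
        stop_ref_coord = ref_coord_at[pos]
        premature = stop_ref_coord < terminal_start
        if stop_shift != 0:
            return OrfStatus(
                verdict="frameshift",
                events=(OrfEvent("frameshift", shift_start[pos]),),
                predicted_protein_length=protein_length,
            )
        if premature:
            return OrfStatus(
                verdict="premature_stop",
                events=(OrfEvent("premature_stop", first_stop_codon),),
                predicted_protein_length=protein_length,
            )
        return OrfStatus(verdict="intact", predicted_protein_length=protein_length)

    # no stop anywhere: intact only if the frame ends unshifted
    if shift != 0:
        return OrfStatus(
            verdict="frameshift",
            events=(OrfEvent("frameshift", min(stretch_start, len(orth) - 1)),),
            predicted_protein_length=protein_length,
        )
    return OrfStatus(verdict="intact", predicted_protein_length=protein_length)


def assign_clade(
    gene_id: str, statuses: Mapping[str, OrfStatus], tree: SpeciesTree
) -> CladeAssignment:
    """Date a gene's origin as the MRCA clade of its intact orthologs.

    The human ortholog must be intact (the catalogue is built from genes
    observed in the human transcriptome); species with broken or missing
    orthologs never pull the assignment tipward.
    """
    if not statuses:
        raise ValueError("no statuses given")
    human = statuses.get("human")
    if human is None or not human.intact:
        raise ValueError(f"{gene_id}: human ortholog must be intact to assign a clade")
    intact = [sp for sp, st in statuses.items() if st.intact]
    origin = tree.mrca_clade(intact)
    return CladeAssignment(gene_id=gene_id, origin=origin, statuses=dict(statuses))


def branch_birth_rates(
    assignments: Iterable[CladeAssignment | str],
    tree: SpeciesTree,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-birth counts and rates per clade branch, with Poisson outliers.

    ``assignments`` may be :class:`CladeAssignment` objects or bare clade
    labels.  The global rate is total births over total branch length; a
    branch is an outlier when its exact Poisson upper-tail probability
    P(X >= count) under expectation rate*length falls below ``alpha``.
    """
    labels = [a.origin if isinstance(a, CladeAssignment) else a for a in assignments]
    branches = tree.clade_labels
    unknown = set(labels) - set(branches)
    if unknown:
        raise ValueError(f"assignments to unknown branches: {sorted(unknown)}")
    lengths = {b: tree.branch_length(b) for b in branches}
    total_length = sum(lengths.values())
    if total_length <= 0:
        raise ValueError("total branch length must be positive")
    counts = {b: labels.count(b) for b in branches}
    lam = sum(counts.values()) / total_length
    rows = []
    for b in branches:
        expected = lam * lengths[b]
        # exact upper tail P(X >= k)
        p = float(poisson.sf(counts[b] - 1, expected)) if counts[b] > 0 else 1.0
        rows.append(
            {
                "branch": b,
                "count": counts[b],
                "branch_length": lengths[b],
                "rate": counts[b] / lengths[b],
                "expected": expected,
                "poisson_p": p,
                "outlier": p < alpha,
            }
        )
    return pd.DataFrame(rows)
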