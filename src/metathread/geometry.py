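"""Rigid-body superposition, TM-score, and functional-template labeling.

A structure template is called *functional* for a target protein when it
(1) superposes onto the target with a TM-score of at least 0.4 and places its
bound molecular partner (ligand, metal ion, iron-sulfur cluster, partner
protein, or DNA) within an aspect-specific distance of the target's partner
(the *Location* criterion), and (2) binds a chemically similar molecule or
shares the binding mode (the *Features* criterion: ligand Tanimoto >= 0.5,
identical metal element, same AT/GC-rich DNA composition class, or a
protein-protein interface-similarity score >= 0.191).

This module provides the geometric machinery (Kabsch superposition with an
iterative TM-score refinement, partner distances, interface extraction) and
the composite labeling rules, plus the dataset-level filters used to build
benchmark sets of binding proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "BindingAspect",
    "BoundPartner",
    "FunctionalLabel",
    "Structure",
    "Superposition",
    "DISTANCE_THRESHOLDS",
    "TM_SCORE_THRESHOLD",
    "TANIMOTO_THRESHOLD",
    "INTERFACE_SCORE_THRESHOLD",
    "SUPPORTED_METALS",
    "kabsch_superpose",
    "tm_score",
    "optimize_tm_superposition",
    "sequence_identity",
    "min_partner_distance",
    "evaluate_location",
    "tanimoto",
    "classify_nucleotide_composition",
    "extract_interface",
    "interface_overlap_score",
    "evaluate_features",
    "label_template",
    "passes_dataset_filters",
]


class BindingAspect(Enum):
    """The five aspects of molecular function covered by the toolkit."""

    LIGAND = "ligand"
    METAL = "metal"
    FE_S = "fe_s"
    PROTEIN = "protein"
    DNA = "dna"


#: TM-score significance threshold for a structural alignment.
TM_SCORE_THRESHOLD = 0.4

#: Per-aspect partner-distance thresholds (angstrom) for the Location label.
DISTANCE_THRESHOLDS: Mapping[BindingAspect, float] = {
    BindingAspect.LIGAND: 4.0,
    BindingAspect.METAL: 2.0,
    BindingAspect.FE_S: 3.0,
    BindingAspect.PROTEIN: 6.0,
    BindingAspect.DNA: 6.0,
}

#: Tanimoto coefficient threshold for chemically similar ligands.
TANIMOTO_THRESHOLD = 0.5

#: Interface-similarity (IS-score) significance threshold.
INTERFACE_SCORE_THRESHOLD = 0.191

#: Metal elements admitted into the metal-binding dataset.
SUPPORTED_METALS = frozenset({"Ca", "Co", "Cu", "Fe", "Mg", "Mn", "Zn"})

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class BoundPartner:
    """A molecular partner bound to a protein chain.

    ``atoms`` holds heavy-atom coordinates in angstrom. Aspect-specific
    payloads: ``element`` for metal ions, ``fingerprint`` (1024-bit vector)
    for ligands, ``sequence`` for DNA strands, ``interface_residues``
    (0-based ordinal residue positions) for protein partners.
    """

    aspect: BindingAspect
    atoms: np.ndarray
    element: str | None = None
    fingerprint: np.ndarray | None = None
    sequence: str | None = None
    interface_residues: frozenset[int] | None = None
    covalent: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)
        if len(self.atoms) == 0:
            raise ValueError("a bound partner must have at least one atom")
        if self.aspect is BindingAspect.METAL and len(self.atoms) != 1:
            raise ValueError("a metal partner is a single ion")
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=bool).ravel()


@dataclass
class Structure:
    """A CA-trace protein structure with its bound partners.

    ``residues`` is an ordered list of ``(residue_index, one_letter_code)``
    with strictly increasing indices as in the source coordinate file;
    ``ca_coords`` is the matching (n, 3) array of CA positions in angstrom.
    Operations address residues by 0-based ordinal position.
    """

    id: str
    residues: list[tuple[int, str]]
    ca_coords: np.ndarray
    het_groups: list[BoundPartner] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if len(self.residues) == 0:
            raise ValueError("a structure must have at least one residue")
        if len(self.residues) != len(self.ca_coords):
            raise ValueError("residue list and coordinate array disagree in length")
        idx = [i for i, _ in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("coordinates must be finite")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Superposition:
    """A rigid transform mapping a template frame onto a target frame.

    ``x_target ~ rotation @ x_template + translation`` over the residue
    ``pairs`` (template ordinal, target ordinal). ``rmsd`` is over the pairs
    used to fit the transform; ``tm_score`` normalizes by target length.
    """

    rotation: np.ndarray
    translation: np.ndarray
    pairs: list[tuple[int, int]]
    rmsd: float
    tm_score: float | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass
class FunctionalLabel:
    """Outcome of labeling one template against one target.

    ``location_positive`` and ``features_positive`` are independent labels;
    the intermediate quantities they were derived from are kept alongside.
    """

    location_positive: bool
    features_positive: bool
    tm_score: float
    partner_distance: float
    tanimoto: float | None = None
    metal_match: bool | None = None
    composition_match: bool | None = None
    interface_score: float | None = None


# ---------------------------------------------------------------------------
# Superposition and TM-score
# ---------------------------------------------------------------------------

def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Finds the proper rotation R and translation t minimizing
    ``sum_i |R m_i + t - f_i|^2`` over all rigid transforms, via SVD of the
    covariance matrix with the reflection branch forced to a rotation
    (det R = +1).

    Parameters
    ----------
    moving, fixed : (n, 3) arrays of paired coordinates, n >= 3.

    Raises
    ------
    ValueError
        For fewer than 3 pairs, mismatched lengths, or collinear points
        (the rotation is then underdetermined).
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must pair 1:1")
    n = len(moving)
    if n < 3:
        raise ValueError("at least 3 point pairs are required")

    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    m = moving - mc
    f = fixed - fc

    h = m.T @ f
    u, s, vt = np.linalg.svd(h)
    # Collinear points leave the rotation about the line axis free.
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fc - rot @ mc

    resid = m @ rot.T - f
    rmsd = float(np.sqrt((resid**2).sum() / n))
    pairs = [(i, i) for i in range(n)]
    return Superposition(rotation=rot, translation=trans, pairs=pairs, rmsd=rmsd)


def tm_score(pair_distances: Sequence[float], l_target: int) -> float:
    """TM-score of an alignment from post-superposition residue distances.

    ``(1/L) * sum_i 1/(1 + (d_i/d0)^2)`` with the length-dependent scale
    ``d0 = 1.24 (L-15)^(1/3) - 1.8``, normalized by the target length L and
    floored at 0.5 angstrom (the formula goes non-positive for L <= 21).
    """
    d = np.asarray(pair_distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if l_target < 1:
        raise ValueError("target length must be >= 1")
    if d.size > l_target:
        raise ValueError("more aligned pairs than target residues")
    d0 = tm_d0(l_target)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)


def tm_d0(l_target: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 angstrom."""
    return max(0.5, 1.24 * np.cbrt(l_target - 15.0) - 1.8)


def optimize_tm_superposition(
    template: Structure,
    target: Structure,
    pairs: Sequence[tuple[int, int]],
    *,
    initial_cutoff: float = 3.5,
    n_expansions: int = 2,
    min_subset: int = 4,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> Superposition:
    """TM-score-maximizing superposition by iterative subset re-fitting.

    Starts from the all-pair Kabsch transform, then repeatedly re-superposes
    on the subset of pairs closer than a cutoff (schedule: ``initial_cutoff``
    plus ``n_expansions`` rounds of +1 angstrom), keeping the transform with
    the highest TM-score seen. This rewards a well-fitting core over a few
    displaced segments, mimicking how TM-score-optimal alignments behave.
    The result never scores below the plain all-pair superposition.
    """
    pairs = [(int(a), int(b)) for a, b in pairs]
    if len(pairs) < 3:
        raise ValueError("at least 3 pairs are required")
    tpl_xyz = template.ca_coords[[a for a, _ in pairs]]
    tgt_xyz = target.ca_coords[[b for _, b in pairs]]
    l_target = len(target)

    def score(sup: Superposition) -> float:
        d = np.linalg.norm(sup.apply(tpl_xyz) - tgt_xyz, axis=1)
        return tm_score(d, l_target)

    best = kabsch_superpose(tpl_xyz, tgt_xyz)
    best_tm = score(best)

    current = best
    for round_ in range(n_expansions + 1):
        cutoff = initial_cutoff + round_
        prev_tm = -np.inf
        for _ in range(max_iter):
            d = np.linalg.norm(current.apply(tpl_xyz) - tgt_xyz, axis=1)
            keep = d < cutoff
            if keep.sum() < min_subset:
                break
            try:
                sub = kabsch_superpose(tpl_xyz[keep], tgt_xyz[keep])
            except ValueError:  # collinear subset
                break
            current = sub
            tm = score(sub)
            if tm > best_tm:
                best, best_tm = sub, tm
            if tm - prev_tm < tol:
                break
            prev_tm = tm

    best.pairs = pairs
    best.tm_score = best_tm
    return best


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent sequence identity between two protein chains.

    Needleman-Wunsch with BLOSUM62, gap open -11 / extend -1; identity is
    the number of identical aligned positions over the alignment length
    (gap columns included), times 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        if any(c not in _AMINO_ACIDS for c in s.upper()):
            raise ValueError("sequences must use the 20-letter amino-acid alphabet")
    aln = _global_aligner().align(seq_a.upper(), seq_b.upper())[0]
    a_idx, b_idx = aln.aligned
    # alignment length = aligned columns + unaligned residues on both sides
    ident = sum(
        1
        for (a0, a1), (b0, b1) in zip(a_idx, b_idx)
        for i, j in zip(range(a0, a1), range(b0, b1))
        if seq_a.upper()[i] == seq_b.upper()[j]
    )
    aligned_cols = sum(a1 - a0 for a0, a1 in a_idx)
    length = len(seq_a) + len(seq_b) - aligned_cols
    return 100.0 * ident / length


def _global_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


# ---------------------------------------------------------------------------
# Partner geometry and chemical similarity
# ---------------------------------------------------------------------------

def min_partner_distance(
    template_atoms: np.ndarray,
    target_atoms: np.ndarray,
    superposition: Superposition,
) -> float:
    """Minimum heavy-atom distance between superposed template and target partners.

    Template partner atoms are mapped into the target frame first; for metal
    ions this reduces to the ion-ion distance.
    """
    template_atoms = np.asarray(template_atoms, dtype=float).reshape(-1, 3)
    target_atoms = np.asarray(target_atoms, dtype=float).reshape(-1, 3)
    if len(template_atoms) == 0 or len(target_atoms) == 0:
        raise ValueError("partner atom lists must be non-empty")
    moved = superposition.apply(template_atoms)
    return float(cdist(moved, target_atoms).min())


def evaluate_location(aspect: BindingAspect, tm: float, distance: float) -> bool:
    """Location criterion: significant superposition and nearby partner.

    True iff the template-to-target TM-score is >= 0.4 and the partner
    distance is within the aspect threshold (4/2/3/6/6 angstrom for
    ligand/metal/Fe-S/protein/DNA; both thresholds inclusive).
    """
    if aspect not in DISTANCE_THRESHOLDS:
        raise ValueError(f"unknown binding aspect: {aspect!r}")
    return tm >= TM_SCORE_THRESHOLD and distance <= DISTANCE_THRESHOLDS[aspect]


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |A&B| / |A|B| of two binary fingerprints."""
    a = np.asarray(fp_a, dtype=bool).ravel()
    b = np.asarray(fp_b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return float(np.logical_and(a, b).sum() / union)


def classify_nucleotide_composition(seq: str) -> str:
    """Classify a DNA sequence as AT_RICH, GC_RICH, or BALANCED.

    BALANCED is the exact 50/50 tie; by convention it matches neither rich
    class in the Features comparison.
    """
    if not seq:
        raise ValueError("empty DNA sequence")
    s = seq.upper()
    if any(c not in "ACGT" for c in s):
        raise ValueError("DNA sequence must contain only A, C, G, T")
    at = (s.count("A") + s.count("T")) / len(s)
    if at > 0.5:
        return "AT_RICH"
    if at < 0.5:
        return "GC_RICH"
    return "BALANCED"


def extract_interface(
    chain_a: Structure, chain_b: Structure, contact_cutoff: float = 8.0
) -> frozenset[int]:
    """Interfacial residues of chain_a: any CA within cutoff of a chain_b CA.

    A CA-CA contact definition at 8 angstrom, the coarse standard when only
    CA traces are available. Returns 0-based ordinal positions on chain_a.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    d = cdist(chain_a.ca_coords, chain_b.ca_coords)
    return frozenset(np.nonzero((d <= contact_cutoff).any(axis=1))[0].tolist())


def interface_overlap_score(
    target_interface: Iterable[int],
    template_interface: Iterable[int],
    superposition: Superposition,
) -> float:
    """Fraction of target-interface residues matched by template-interface residues.

    A target interface residue counts as matched when the superposition's
    residue correspondence maps it to a residue that is itself interfacial on
    the template. A surrogate for an interface-similarity score, used only
    when externally computed IS-scores are not supplied.
    """
    target_interface = set(target_interface)
    template_interface = set(template_interface)
    if not target_interface:
        raise ValueError("target interface must be non-empty")
    to_template = {tgt: tpl for tpl, tgt in superposition.pairs}
    matched = sum(
        1
        for r in target_interface
        if to_template.get(r) in template_interface
    )
    return matched / len(target_interface)


def evaluate_features(
    aspect: BindingAspect,
    target_payload: BoundPartner,
    template_payload: BoundPartner,
    interface_score: float | None = None,
) -> bool:
    """Features criterion: chemical and geometrical conservation of binding.

    Ligands: Tanimoto >= 0.5. Metals: identical element. DNA: same AT/GC
    composition class (the exact-tie BALANCED class matches nothing).
    Protein: interface-similarity score >= 0.191. Fe/S clusters: identical
    cluster stoichiometry (equal Fe and S counts, e.g. Fe2S2 vs Fe4S4).
    """
    if target_payload.aspect is not aspect or template_payload.aspect is not aspect:
        raise ValueError("payload aspect does not match the requested aspect")
    if aspect is BindingAspect.LIGAND:
        if target_payload.fingerprint is None or template_payload.fingerprint is None:
            raise ValueError("ligand payloads require fingerprints")
        return tanimoto(target_payload.fingerprint, template_payload.fingerprint) >= TANIMOTO_THRESHOLD
    if aspect is BindingAspect.METAL:
        if not target_payload.element or not template_payload.element:
            raise ValueError("metal payloads require an element")
        return target_payload.element == template_payload.element
    if aspect is BindingAspect.DNA:
        if target_payload.sequence is None or template_payload.sequence is None:
            raise ValueError("DNA payloads require sequences")
        cls_t = classify_nucleotide_composition(target_payload.sequence)
        cls_p = classify_nucleotide_composition(template_payload.sequence)
        return cls_t == cls_p and cls_t != "BALANCED"
    if aspect is BindingAspect.PROTEIN:
        if interface_score is None:
            raise ValueError("protein aspect requires an interface score")
        return interface_score >= INTERFACE_SCORE_THRESHOLD
    if aspect is BindingAspect.FE_S:
        return _fes_stoichiometry(target_payload) == _fes_stoichiometry(template_payload)
    raise ValueError(f"unknown binding aspect: {aspect!r}")


def _fes_stoichiometry(partner: BoundPartner) -> tuple[int, int]:
    """(n_Fe, n_S) of an iron-sulfur cluster, from its name or atom count.

    Cluster names follow PDB chemical-component conventions (SF4 = Fe4S4,
    FES = Fe2S2, F3S = Fe3S4); unnamed clusters fall back to an even split
    of the atom count.
    """
    known = {"SF4": (4, 4), "FES": (2, 2), "F3S": (3, 4), "FE2S2": (2, 2), "FE4S4": (4, 4)}
    if partner.name.upper() in known:
        return known[partner.name.upper()]
    n = len(partner.atoms)
    return (n // 2, n - n // 2)


# ---------------------------------------------------------------------------
# Composite labeling and dataset filters
# ---------------------------------------------------------------------------

def label_template(
    target: Structure,
    target_partner: BoundPartner,
    template: Structure,
    template_partner: BoundPartner,
    *,
    pairs: Sequence[tuple[int, int]] | None = None,
    interface_score: float | None = None,
) -> FunctionalLabel:
    """Label one template against one target for one binding aspect.

    Composes superposition -> TM-score -> partner distance -> Location rule,
    and the aspect's payload comparison -> Features rule, recording every
    intermediate quantity. Residue correspondences may be supplied (e.g. from
    an external structure aligner); otherwise a Needleman-Wunsch sequence
    alignment provides them. For the protein aspect, an externally computed
    interface-similarity score takes precedence over the built-in
    interface-overlap surrogate.
    """
    aspect = target_partner.aspect
    if template_partner.aspect is not aspect:
        raise ValueError("target and template partners must share an aspect")
    if pairs is None:
        pairs = _alignment_pairs(template.sequence, target.sequence)
    sup = optimize_tm_superposition(template, target, pairs)
    dist = min_partner_distance(template_partner.atoms, target_partner.atoms, sup)
    loc = evaluate_location(aspect, sup.tm_score, dist)

    tc = metal_match = comp_match = None
    is_score = interface_score
    if aspect is BindingAspect.PROTEIN and is_score is None:
        tgt_if = target_partner.interface_residues
        tpl_if = template_partner.interface_residues or frozenset()
        if tgt_if:
            is_score = interface_overlap_score(tgt_if, tpl_if, sup)
    feat = evaluate_features(aspect, target_partner, template_partner, is_score)
    if aspect is BindingAspect.LIGAND:
        tc = tanimoto(target_partner.fingerprint, template_partner.fingerprint)
    elif aspect is BindingAspect.METAL:
        metal_match = feat
    elif aspect is BindingAspect.DNA:
        comp_match = feat
    return FunctionalLabel(
        location_positive=loc,
        features_positive=feat,
        tm_score=sup.tm_score,
        partner_distance=dist,
        tanimoto=tc,
        metal_match=metal_match,
        composition_match=comp_match,
        interface_score=is_score,
    )


def _alignment_pairs(seq_template: str, seq_target: str) -> list[tuple[int, int]]:
    """Residue correspondences from a global Needleman-Wunsch alignment."""
    aln = _global_aligner().align(seq_template, seq_target)[0]
    a_idx, b_idx = aln.aligned
    return [
        (i, j)
        for (a0, a1), (b0, b1) in zip(a_idx, b_idx)
        for i, j in zip(range(a0, a1), range(b0, b1))
    ]


def passes_dataset_filters(
    structure: Structure, partner: BoundPartner, aspect: BindingAspect | None = None
) -> bool:
    """Benchmark dataset admission rules for one protein/partner entry.

    The chain must be 50-600 residues long and the partner must satisfy its
    aspect rule: ligands with 7-60 heavy atoms bound non-covalently; DNA of
    at least 10 nucleotides; protein partners with at least 20 interfacial
    residues; metal ions from {Ca, Co, Cu, Fe, Mg, Mn, Zn}; Fe/S clusters
    with at least two irons and two sulfurs.
    """
    aspect = aspect or partner.aspect
    if not 50 <= len(structure) <= 600:
        return False
    if aspect is BindingAspect.LIGAND:
        return 7 <= len(partner.atoms) <= 60 and not partner.covalent
    if aspect is BindingAspect.METAL:
        return partner.element in SUPPORTED_METALS
    if aspect is BindingAspect.FE_S:
        n_fe, n_s = _fes_stoichiometry(partner)
        return n_fe >= 2 and n_s >= 2 and len(partner.atoms) >= 4
    if aspect is BindingAspect.DNA:
        return partner.sequence is not None and len(partner.sequence) >= 10
    if aspect is BindingAspect.PROTEIN:
        return (
            partner.interface_residues is not None
            and len(partner.interface_residues) >= 20
        )
    raise ValueError(f"unknown binding aspect: {aspect!r}")
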