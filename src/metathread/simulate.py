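"""Synthetic fixtures with the statistical and geometric structure the method assumes.

Generators for (a) threading score tables with known class-conditional
Gaussians and ground-truth labels, (b) idealized CA-trace structures and
noisy template copies with a known rigid transform, (c) fingerprint pairs
with a prescribed Tanimoto coefficient, and (d) DNA sequences with exact
AT/GC composition. Every generator is a pure function of its seed, so
fixtures compose without order sensitivity and reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import THREADING_METHODS, TemplateRecord
from .geometry import BindingAspect, BoundPartner, Structure

__all__ = [
    "ScoreSimSpec",
    "simulate_score_records",
    "make_toy_structure",
    "make_template_from_target",
    "simulate_fingerprint_pair",
    "simulate_dna",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _default_means_pos() -> dict[str, float]:
    return {m: 1.0 for m in THREADING_METHODS}


def _default_means_neg() -> dict[str, float]:
    return {m: 0.0 for m in THREADING_METHODS}


def _default_sds() -> dict[str, float]:
    return {m: 1.0 for m in THREADING_METHODS}


@dataclass
class ScoreSimSpec:
    """Generating model for a synthetic threading score table.

    Per method, scores are class-conditional Gaussians; the defaults emulate
    a moderately informative threading method (positive templates one pooled
    SD above negatives, per-method AUC ~ 0.76, in the range observed for
    real single-threading programs), with a class prior of 0.2 positives
    (positives/negatives ratios for the Location criterion run ~0.10-0.87
    across binding aspects) and 10% of scores missing (not every method
    ranks every template). ``latent_loading`` > 0 adds a shared standard
    normal factor to every method's score, inducing the inter-method
    correlation real threading scores exhibit (default: independent).
    """

    means_pos: dict[str, float] = field(default_factory=_default_means_pos)
    means_neg: dict[str, float] = field(default_factory=_default_means_neg)
    sds_pos: dict[str, float] = field(default_factory=_default_sds)
    sds_neg: dict[str, float] = field(default_factory=_default_sds)
    class_prior: float = 0.2
    n_templates: int = 1000
    missing_rate: float = 0.1
    latent_loading: float = 0.0
    templates_per_target: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_prior < 1.0:
            raise ValueError("class prior must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        for sds in (self.sds_pos, self.sds_neg):
            if any(s <= 0 for s in sds.values()):
                raise ValueError("score SDs must be positive")

    @classmethod
    def separated(cls, delta_mu: float, **kw) -> "ScoreSimSpec":
        """Spec with all-method class separation of ``delta_mu`` (unit SDs)."""
        return cls(
            means_pos={m: delta_mu for m in THREADING_METHODS},
            means_neg={m: 0.0 for m in THREADING_METHODS},
            **kw,
        )


def simulate_score_records(
    spec: ScoreSimSpec, aspect: BindingAspect = BindingAspect.LIGAND
) -> list[TemplateRecord]:
    """Draw labeled template records from the spec's generating model.

    Labels are Bernoulli(class_prior); each present score is drawn from the
    label's Gaussian for that method; scores are masked missing at
    ``missing_rate`` (at least one score always survives per record).
    Records are grouped into targets of ``templates_per_target`` templates,
    giving the grouped cross-validation something to group by. Both the
    Location and Features labels are set to the drawn ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    methods = list(spec.means_pos)
    records: list[TemplateRecord] = []
    for i in range(spec.n_templates):
        positive = bool(rng.random() < spec.class_prior)
        latent = rng.standard_normal() if spec.latent_loading else 0.0
        means = spec.means_pos if positive else spec.means_neg
        sds = spec.sds_pos if positive else spec.sds_neg
        scores = {
            m: float(rng.normal(means[m], sds[m]) + spec.latent_loading * latent)
            for m in methods
        }
        if spec.missing_rate > 0:
            mask = rng.random(len(methods)) < spec.missing_rate
            if mask.all():
                mask[rng.integers(len(methods))] = False
            scores = {m: v for (m, v), drop in zip(scores.items(), mask) if not drop}
        records.append(
            TemplateRecord(
                target_id=f"T{i // spec.templates_per_target:05d}",
                template_id=f"t{i:06d}",
                aspect=aspect,
                scores=scores,
                label_location=positive,
                label_features=positive,
            )
        )
    return records


def make_toy_structure(
    n_res: int, conformation: str = "helix", seed: int = 0, struct_id: str | None = None
) -> Structure:
    """An idealized CA trace: alpha-helix, extended strand, or seeded coil.

    Helix geometry: 1.5 angstrom rise and 100 degrees per residue on a
    2.3 angstrom radius, which reproduces the canonical ~3.8 angstrom
    consecutive CA-CA distance. The strand is a flat zigzag at the same CA
    spacing; the coil is a self-avoiding-ish random walk with fixed 3.8
    angstrom steps. Residue identities are drawn from the seed.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    if conformation == "helix":
        i = np.arange(n_res)
        theta = np.deg2rad(100.0) * i
        xyz = np.c_[2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    elif conformation == "strand":
        i = np.arange(n_res)
        xyz = np.c_[3.63 * i, 1.1 * (-1.0) ** i, np.zeros(n_res)]
    elif conformation == "coil":
        steps = rng.standard_normal((n_res - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        xyz = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
    else:
        raise ValueError(f"unknown conformation: {conformation!r}")
    seq = rng.choice(list(_AA), size=n_res)
    residues = [(i + 1, aa) for i, aa in enumerate(seq)]
    return Structure(
        id=struct_id or f"{conformation}{n_res}s{seed}", residues=residues, ca_coords=xyz
    )


def make_template_from_target(
    target: Structure,
    coord_noise_sd: float = 0.5,
    partner_shift: float = 0.0,
    rigid_seed: int = 0,
) -> tuple[Structure, np.ndarray, np.ndarray]:
    """A noisy, rigidly moved copy of a target (with partner) plus the truth.

    Copies the target's CA trace, adds isotropic Gaussian coordinate noise,
    displaces each bound-partner copy by ``partner_shift`` angstrom along a
    random direction, and applies a random rigid transform to everything.
    Returns ``(template, rotation, translation)`` where the transform maps
    target-frame coordinates into the template frame — its inverse is what a
    correct superposition must recover.
    """
    if not target.het_groups:
        raise ValueError("target must carry at least one bound partner")
    rng = np.random.default_rng(rigid_seed)
    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)

    ca = target.ca_coords + rng.normal(0.0, coord_noise_sd, size=target.ca_coords.shape)
    ca = ca @ rot.T + trans
    partners = []
    for p in target.het_groups:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        atoms = (p.atoms + partner_shift * direction) @ rot.T + trans
        partners.append(
            BoundPartner(
                aspect=p.aspect,
                atoms=atoms,
                element=p.element,
                fingerprint=p.fingerprint,
                sequence=p.sequence,
                interface_residues=p.interface_residues,
                covalent=p.covalent,
                name=p.name,
            )
        )
    template = Structure(
        id=f"{target.id}_tpl{rigid_seed}",
        residues=list(target.residues),
        ca_coords=ca,
        het_groups=partners,
    )
    return template, rot, trans


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix (sign-fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_fingerprint_pair(
    n_bits: int = 1024, target_tc: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two binary fingerprints whose Tanimoto equals ``target_tc`` within 1/n_bits.

    Constructive: choose a union of u bits and an intersection of
    ``round(target_tc * u)`` bits, splitting the symmetric difference evenly;
    bit positions are then shuffled by the seed. Raises when no feasible
    (intersection, union) pair exists at the requested precision.
    """
    if not 0.0 <= target_tc <= 1.0:
        raise ValueError("target Tanimoto must be in [0, 1]")
    if n_bits < 2:
        raise ValueError("need at least 2 bits")
    # pick the union size whose best integer intersection lands closest to
    # the target (exact for rationals like 1/2); prefer ~90% bit density
    anchor = max(2, int(0.9 * n_bits))
    best = min(
        range(2, n_bits + 1),
        key=lambda u: (abs(round(target_tc * u) / u - target_tc), abs(u - anchor)),
    )
    union = best
    inter = round(target_tc * union)
    if abs(inter / union - target_tc) > 1.0 / n_bits:
        raise ValueError("target Tanimoto infeasible at this bit density")
    rng = np.random.default_rng(seed)
    positions = rng.permutation(n_bits)[:union]
    common = positions[:inter]
    rest = positions[inter:]
    a_only = rest[: len(rest) // 2]
    b_only = rest[len(rest) // 2 :]
    fp_a = np.zeros(n_bits, dtype=bool)
    fp_b = np.zeros(n_bits, dtype=bool)
    fp_a[common] = fp_a[a_only] = True
    fp_b[common] = fp_b[b_only] = True
    if target_tc == 1.0:
        fp_b = fp_a.copy()
    return fp_a, fp_b


def simulate_dna(length: int, at_fraction: float, seed: int = 0) -> str:
    """A DNA string with exactly ``round(length * at_fraction)`` A/T bases.

    The A/T and G/C characters are drawn uniformly within their class and
    the sequence is shuffled deterministically by the seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_at = round(length * at_fraction)
    chars = list(rng.choice(["A", "T"], size=n_at)) + list(
        rng.choice(["G", "C"], size=length - n_at)
    )
    rng.shuffle(chars)
    return "".join(chars)
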