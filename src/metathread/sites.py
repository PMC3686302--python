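"""Posterior-weighted consensus binding-site prediction.

After superposing functional templates onto the target, the centers of mass
of their bound partners pile up near the true binding site. Clustering those
centers and weighting each cluster by the sum of its members' classifier
posteriors yields ranked site predictions; the weighting lets a few
high-confidence templates outvote a numerous but low-confidence crowd, which
plain majority voting cannot do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .geometry import BoundPartner

__all__ = ["RankedSite", "partner_center", "predict_sites"]


@dataclass
class RankedSite:
    """A predicted binding site: a weighted cluster of partner centers.

    ``center`` is the (optionally posterior-weighted) mean of the member
    centers; ``weight`` is the sum of member posteriors and sets the rank
    (rank 1 = heaviest).
    """

    center: np.ndarray
    weight: float
    members: list[tuple[str, np.ndarray, float]]
    rank: int


def partner_center(partner: BoundPartner | np.ndarray) -> np.ndarray:
    """Geometric center of a bound partner's heavy atoms (equal masses)."""
    atoms = partner.atoms if isinstance(partner, BoundPartner) else np.asarray(partner, float)
    atoms = atoms.reshape(-1, 3)
    if len(atoms) == 0:
        raise ValueError("partner has no atoms")
    return atoms.mean(axis=0)


def predict_sites(
    entries: Sequence[tuple[str, np.ndarray, float]],
    cluster_cutoff: float = 8.0,
    min_posterior: float = 0.0,
    *,
    weight_centers: bool = True,
    weight_ranking: bool = True,
) -> list[RankedSite]:
    """Cluster superposed partner centers into ranked binding-site predictions.

    Parameters
    ----------
    entries
        ``(template_id, center_xyz, posterior)`` triples; centers are partner
        centers of mass already mapped into the target frame.
    cluster_cutoff
        Average-linkage cut height in angstrom (default 8).
    min_posterior
        Entries below this posterior are discarded before clustering;
        typically the Location model's optimal ROC cutoff for the aspect.
    weight_centers, weight_ranking
        Whether posteriors weight the cluster centers and/or the ranking.
        With both off this degrades to plain majority voting by cluster size.

    Returns sites ordered by rank; the summed weight over all sites equals
    the summed posterior of the retained entries. An empty result (all
    entries filtered out) is returned, not raised.
    """
    if cluster_cutoff <= 0:
        raise ValueError("cluster cutoff must be positive")
    if not entries:
        raise ValueError("no entries to cluster")
    kept = [
        (str(tid), np.asarray(c, dtype=float).reshape(3), float(p))
        for tid, c, p in entries
        if float(p) >= min_posterior
    ]
    if not kept:
        return []
    centers = np.array([c for _, c, _ in kept])
    if len(kept) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(centers), method="average")
        labels = fcluster(z, t=cluster_cutoff, criterion="distance")

    sites: list[RankedSite] = []
    for lab in np.unique(labels):
        members = [kept[i] for i in np.nonzero(labels == lab)[0]]
        pts = np.array([c for _, c, _ in members])
        w = np.array([p for _, _, p in members])
        center = np.average(pts, axis=0, weights=w) if weight_centers else pts.mean(axis=0)
        weight = float(w.sum())
        sites.append(RankedSite(center=center, weight=weight, members=members, rank=0))

    if weight_ranking:
        key = lambda s: (-s.weight, tuple(np.round(s.center, 9)))
    else:
        key = lambda s: (-len(s.members), tuple(np.round(s.center, 9)))
    sites.sort(key=key)
    for i, s in enumerate(sites, start=1):
        s.rank = i
    return sites
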