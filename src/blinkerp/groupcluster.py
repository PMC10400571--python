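"""Group-level clustering of IC scalp maps with FPR/FDR control.

Subject-level ICA maps (mixing-matrix columns) are clustered across subjects
by greedy agglomeration on absolute cosine similarity, under the constraint
that each subject contributes at most one component per cluster. Because ICA
maps have arbitrary sign, similarity is computed on |cosine| and members are
sign-aligned to the cluster centroid.

Statistical control uses a channel-permutation null: permuting the entries
of a map within a subject preserves its amplitude distribution while
destroying its topography. The false-positive rate of detected clusters is
controlled by testing each cluster's mean within-cluster |cosine| against
that null; the false discovery rate of joining members is controlled by
testing each member's |cosine| to the leave-one-out centroid against the
same null and adjusting across all joins with Benjamini-Hochberg. Both are
thresholded at alpha (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests


@dataclass
class ComponentMap:
    """One subject-level IC scalp map (unit norm, sign-aligned)."""

    subject_id: str
    component_index: int
    map: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.map, dtype=float)
        norm = np.linalg.norm(m)
        if norm == 0:
            raise ValueError("component map must be non-zero")
        m = m / norm
        if m[np.abs(m).argmax()] < 0:  # largest-|value| entry positive
            m = -m
        self.map = m


@dataclass
class Cluster:
    members: list  # (subject_id, component_index)
    centroid: np.ndarray  # unit norm
    cluster_p: float = np.nan
    mean_similarity: float = np.nan
    member_p: list = field(default_factory=list)
    member_q: list = field(default_factory=list)


@dataclass
class ClusterResult:
    clusters: list  # retained clusters (cluster_p <= alpha, members q <= alpha)
    alpha: float
    candidates: list = field(default_factory=list)  # pre-threshold clusters


def _aligned_mean(vectors: np.ndarray, reference: np.ndarray) -> np.ndarray:
    signs = np.sign(vectors @ reference)
    signs[signs == 0] = 1.0
    mean = (vectors * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean)
    return mean / norm if norm > 0 else reference


def _mean_pairwise_abs_cos(vectors: np.ndarray) -> float:
    gram = np.abs(vectors @ vectors.T)
    k = len(vectors)
    return float((gram.sum() - k) / (k * (k - 1)))


def _greedy_clusters(maps: list[ComponentMap], seed_threshold: float):
    """Greedy seeded agglomeration with subject uniqueness."""
    vectors = np.stack([m.map for m in maps])
    subjects = np.array([m.subject_id for m in maps], dtype=object)
    sim = np.abs(vectors @ vectors.T)
    np.fill_diagonal(sim, 0.0)
    used = np.zeros(len(maps), dtype=bool)
    clusters = []
    while True:
        cross = sim.copy()
        cross[used, :] = 0.0
        cross[:, used] = 0.0
        cross[subjects[:, None] == subjects[None, :]] = 0.0
        i, j = np.unravel_index(np.argmax(cross), cross.shape)
        if cross[i, j] < seed_threshold:
            break
        member_idx = [i, j]
        centroid = _aligned_mean(vectors[[i, j]], vectors[i])
        for subj in sorted(set(subjects) - {subjects[i], subjects[j]}):
            cand = np.flatnonzero((subjects == subj) & ~used)
            if cand.size == 0:
                continue
            sims = np.abs(vectors[cand] @ centroid)
            best = cand[int(np.argmax(sims))]
            if sims.max() >= seed_threshold:  # subject's best component only
                member_idx.append(int(best))
                centroid = _aligned_mean(vectors[member_idx], centroid)
        used[member_idx] = True
        clusters.append(member_idx)
    return vectors, subjects, clusters


def cluster_maps(maps, alpha: float = 0.05, rng_seed: int = 0,
                 seed_threshold: float = 0.7,
                 n_permutations: int = 999) -> ClusterResult:
    """Cluster subject-level IC maps with FPR/FDR control at ``alpha``.

    Deterministic given ``rng_seed``. Requires maps from at least two
    subjects. Retained clusters have a permutation cluster p-value
    ``<= alpha`` and only members whose BH-adjusted join statistic is
    ``<= alpha``; a retained cluster keeps at least two members.
    """
    maps = list(maps)
    if len({m.subject_id for m in maps}) < 2:
        raise ValueError("clustering requires maps from >= 2 subjects")
    rng = np.random.default_rng(rng_seed)
    vectors, subjects, member_lists = _greedy_clusters(maps, seed_threshold)

    candidates = []
    all_member_p = []
    for member_idx in member_lists:
        vecs = vectors[member_idx]
        centroid = _aligned_mean(vecs, vecs[0])
        obs_cluster = _mean_pairwise_abs_cos(vecs)
        # leave-one-out centroids for the member join statistic
        loo = []
        for k in range(len(member_idx)):
            others = np.delete(np.arange(len(member_idx)), k)
            loo.append(_aligned_mean(vecs[others], centroid))
        obs_member = np.abs(np.einsum("ij,ij->i", vecs, np.stack(loo)))

        null_cluster = np.empty(n_permutations)
        null_member = np.empty((n_permutations, len(member_idx)))
        for b in range(n_permutations):
            perm = np.stack([v[rng.permutation(v.size)] for v in vecs])
            null_cluster[b] = _mean_pairwise_abs_cos(perm)
            null_member[b] = np.abs(
                np.einsum("ij,ij->i", perm, np.stack(loo)))
        cluster_p = (1.0 + np.sum(null_cluster >= obs_cluster)) \
            / (n_permutations + 1.0)
        member_p = (1.0 + (null_member >= obs_member[None, :]).sum(axis=0)) \
            / (n_permutations + 1.0)
        all_member_p.extend(member_p)
        candidates.append(Cluster(
            members=[(maps_i.subject_id, maps_i.component_index)
                     for maps_i in (maps[i] for i in member_idx)],
            centroid=centroid, cluster_p=float(cluster_p),
            mean_similarity=obs_cluster, member_p=list(map(float, member_p))))

    if all_member_p:  # BH across every join in every candidate cluster
        _, qvals, _, _ = multipletests(all_member_p, method="fdr_bh")
        pos = 0
        for cl in candidates:
            k = len(cl.member_p)
            cl.member_q = list(map(float, qvals[pos:pos + k]))
            pos += k

    retained = []
    for cl in candidates:
        if cl.cluster_p > alpha:
            continue
        keep = [i for i, q in enumerate(cl.member_q) if q <= alpha]
        if len(keep) < 2:
            continue
        retained.append(Cluster(
            members=[cl.members[i] for i in keep],
            centroid=cl.centroid, cluster_p=cl.cluster_p,
            mean_similarity=cl.mean_similarity,
            member_p=[cl.member_p[i] for i in keep],
            member_q=[cl.member_q[i] for i in keep]))
    return ClusterResult(clusters=retained, alpha=alpha,
                         candidates=candidates)


def select_roi_clusters(result: ClusterResult, dipole_fits, roi_label: str,
                        known_labels=None) -> dict:
    """Per-subject component subsets from clusters whose dipole matches a ROI.

    ``dipole_fits`` aligns with ``result.clusters`` (objects with a
    ``label`` attribute or plain strings). Returns ``{subject_id: sorted
    list of component indices}`` over clusters labelled ``roi_label``; an
    empty selection is allowed (with a warning).
    """
    labels = [getattr(f, "label", f) for f in dipole_fits]
    if len(labels) != len(result.clusters):
        raise ValueError("need exactly one dipole fit per retained cluster")
    vocabulary = set(known_labels) if known_labels is not None \
        else set(labels)
    if roi_label not in vocabulary:
        raise ValueError(
            f"unknown ROI label {roi_label!r}; available: "
            f"{sorted(vocabulary)}")
    selection: dict[str, set] = {}
    matched = False
    for cl, label in zip(result.clusters, labels):
        if label != roi_label:
            continue
        matched = True
        for subject_id, comp in cl.members:
            selection.setdefault(subject_id, set()).add(comp)
    if not matched:
        warnings.warn(f"no retained cluster labelled {roi_label!r}; "
                      "empty selection", stacklevel=2)
    return {s: sorted(c) for s, c in selection.items()}
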