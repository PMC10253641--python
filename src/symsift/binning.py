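"""Composition binning: k-mer profiles and bootstrap consensus clustering.

Contigs are represented by penta-nucleotide (k=5 by default) frequency
vectors, reduced by PCA, and clustered with a bootstrap k-medoids
consensus: the contig set is resampled ``n_bootstrap`` times, every contig
is assigned to the nearest medoid of each resample's clustering, and the
fraction of replicates in which two contigs land in the same cluster
forms a co-assignment matrix.  Final bins are an average-linkage cut of
(1 - co-assignment), and each contig's confidence is its mean
co-assignment with its own final bin; low-confidence contigs are flagged
unbinned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

_BASES = "ACGT"


@dataclass
class KmerProfile:
    contig_id: str
    frequencies: np.ndarray  # length 4^k, sums to 1 (zero vector if too short)
    contig_length: int
    k: int

    @property
    def degenerate(self) -> bool:
        return float(self.frequencies.sum()) == 0.0


def kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in product(_BASES, repeat=k)]


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[raw == ord(b)] = i
    return codes


def kmer_profile(
    sequence: str, k: int = 5, contig_id: str = "", canonical: bool = False
) -> KmerProfile:
    """Normalized k-mer frequency vector over all ACGT-only windows.

    Windows containing non-ACGT symbols are skipped; sequences shorter
    than k yield a flagged zero vector.  With ``canonical=True`` each
    window is pooled with its reverse complement (forward strand only by
    default).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence)
    dim = 4**k
    if n < k:
        return KmerProfile(contig_id, np.zeros(dim), n, k)
    codes = _encode(sequence)
    valid = codes >= 0
    # rolling base-4 window codes
    win = np.zeros(n - k + 1, dtype=np.int64)
    win_valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        win = win * 4 + np.where(valid[j : j + n - k + 1], codes[j : j + n - k + 1], 0)
        win_valid &= valid[j : j + n - k + 1]
    counts = np.bincount(win[win_valid], minlength=dim).astype(float)
    if canonical:
        rc = _revcomp_index(k)
        counts = counts + counts[rc]
    total = counts.sum()
    if total == 0:
        return KmerProfile(contig_id, np.zeros(dim), n, k)
    return KmerProfile(contig_id, counts / total, n, k)


def _revcomp_index(k: int) -> np.ndarray:
    idx = np.arange(4**k)
    out = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(k):
        out = out * 4 + (3 - (tmp % 4))
        tmp //= 4
    return out


@dataclass
class BinAssignment:
    contig_id: str
    bin_label: int
    confidence: float  # bootstrap co-assignment consistency, in [0, 1]
    unbinned: bool


def _kmedoids(
    dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50
) -> np.ndarray:
    """Voronoi-iteration k-medoids on a precomputed distance matrix.

    Returns the medoid row indices.  Deterministic given rng state.
    """
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return medoids


def bootstrap_bin(
    profiles: list[KmerProfile],
    n_clusters: int | str = 2,
    n_bootstrap: int = 100,
    co_assign_threshold: float = 0.8,
    seed: int = 0,
    n_components: int = 10,
) -> list[BinAssignment]:
    """Bootstrap k-medoids consensus binning of k-mer profiles.

    Pipeline: PCA to ``n_components`` -> k-medoids on ``n_bootstrap``
    resamples (every contig assigned to the nearest medoid of each
    resample) -> co-assignment matrix -> final bins by average-linkage cut
    -> confidence = mean co-assignment with the contig's own final bin.
    ``n_clusters="auto"`` picks the best mean silhouette over k in 2..6.
    """
    n = len(profiles)
    if n == 0:
        return []
    dims = {p.frequencies.shape[0] for p in profiles}
    if len(dims) != 1:
        raise ValueError("profiles must share one k-mer dimension")
    if n == 1:
        return [BinAssignment(profiles[0].contig_id, 0, 1.0, False)]

    # canonicalize on contig id so input order cannot influence the
    # resampling stream: bin composition is then permutation-invariant
    order = sorted(range(n), key=lambda i: profiles[i].contig_id)
    rank = {orig: pos for pos, orig in enumerate(order)}
    profiles_sorted = [profiles[i] for i in order]

    X = np.stack([p.frequencies for p in profiles_sorted])
    rng = np.random.default_rng(seed)
    d = min(n_components, n - 1, X.shape[1])
    emb = PCA(n_components=d, random_state=0).fit_transform(X)
    dist = cdist(emb, emb)
    # identical profiles must behave identically under tie-breaking:
    # snap numerically-zero distances so duplicates always co-assign
    dist[dist < 1e-12] = 0.0

    if n_clusters == "auto":
        best_k, best_score = 2, -np.inf
        for k in range(2, min(6, n - 1) + 1):
            medoids = _kmedoids(dist, k, np.random.default_rng([seed, 10_000 + k]))
            labels = np.argmin(dist[:, medoids], axis=1)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(emb, labels)
            if score > best_score:
                best_k, best_score = k, score
        n_clusters = best_k
    n_clusters = int(n_clusters)
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of contigs {n}")

    co = np.zeros((n, n))
    for b in range(n_bootstrap):
        brng = np.random.default_rng([seed, b])
        sample = np.unique(brng.choice(n, size=n, replace=True))
        if sample.size < n_clusters:
            sample = np.arange(n)
        medoids = sample[
            _kmedoids(dist[np.ix_(sample, sample)], n_clusters, brng)
        ]
        labels = np.argmin(dist[:, medoids], axis=1)
        co += labels[:, None] == labels[None, :]
    co /= n_bootstrap

    consensus_dist = 1.0 - co
    np.fill_diagonal(consensus_dist, 0.0)
    z = linkage(squareform(consensus_dist, checks=False), method="average")
    final = fcluster(z, t=n_clusters, criterion="maxclust") - 1

    out = []
    for orig, p in enumerate(profiles):
        i = rank[orig]
        members = np.flatnonzero(final == final[i])
        conf = float(co[i, members].mean())
        out.append(
            BinAssignment(
                contig_id=p.contig_id,
                bin_label=int(final[i]),
                confidence=conf,
                unbinned=conf < co_assign_threshold,
            )
        )
    return out


def assignments_to_frame(assignments: list[BinAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "bin_label": a.bin_label,
                "confidence": a.confidence,
                "unbinned": a.unbinned,
            }
            for a in assignments
        ],
        columns=["contig_id", "bin_label", "confidence", "unbinned"],
    )
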