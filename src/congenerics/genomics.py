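"""Comparative genomics: COG occupancy profiles with PCA, and ortho-group
matrix analytics (core-genome calling, gene accumulation, Heaps' openness
fit, binary-distance embedding, silhouette-selected k-means).

The ortho-group matrix is a genomes x groups table of gene counts.  The
core genome is the set of groups present in at least ``ceil(prevalence *
n_genomes)`` genomes (95% by default, i.e. 41 of 43).  Pan-genome openness
is assessed by fitting Heaps' power law ``n_new(g) = kappa * g**-alpha`` to
the per-step new-group counts of the accumulation curve; ``alpha <= 1``
marks an open pan genome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "COG_CATEGORIES",
    "cog_occupancy",
    "pca",
    "PCAResult",
    "core_genome",
    "accumulation_curve",
    "fit_heaps",
    "HeapsFit",
    "binary_distance",
    "embed_2d",
    "kmeans_silhouette",
    "KMeansResult",
    "transportome_profile",
    "read_gene_records",
]

# single-letter COG functional categories; NIC = not in COG
COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ") | {"NIC"}


# ---------------------------------------------------------------------------
# COG genome occupancy
# ---------------------------------------------------------------------------

def _parse_categories(value) -> frozenset[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        cats = frozenset(str(c) for c in value if str(c))
    else:
        text = "" if value is None or (isinstance(value, float) and math.isnan(value)) \
            else str(value).strip()
        cats = frozenset(c for c in text.split(";") if c)
    cats = cats - {"NIC"}
    bad = {c for c in cats if c not in COG_CATEGORIES}
    if bad:
        raise ValueError(f"unknown COG category codes: {sorted(bad)}")
    return cats if cats else frozenset({"NIC"})


def read_gene_records(path) -> pd.DataFrame:
    """Read a gene table TSV with columns genome_id, gene_id, length_bp,
    cog_categories (semicolon-joined single letters; empty = NIC)."""
    df = pd.read_csv(path, sep="\t", dtype={"cog_categories": str})
    df["cog_categories"] = df["cog_categories"].where(
        df["cog_categories"].notna(), "")
    return df


def cog_occupancy(genes: pd.DataFrame) -> pd.DataFrame:
    """Per-genome nucleotide share of each COG category.

    A gene of length L assigned to k categories contributes L/k to each of
    them ("equal allotment"); genes with no assignment count toward NIC.
    Every genome row sums to 1.
    """
    required = {"genome_id", "gene_id", "length_bp", "cog_categories"}
    if missing := required - set(genes.columns):
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if genes.empty:
        raise ValueError("empty gene table")
    if (genes["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be > 0")

    weights: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    for row in genes.itertuples(index=False):
        cats = _parse_categories(row.cog_categories)
        share = float(row.length_bp) / len(cats)
        gw = weights.setdefault(row.genome_id, {})
        for c in cats:
            gw[c] = gw.get(c, 0.0) + share
        totals[row.genome_id] = totals.get(row.genome_id, 0.0) + float(row.length_bp)

    profile = pd.DataFrame(weights).T.fillna(0.0)
    profile = profile.div(pd.Series(totals), axis=0)
    profile.index.name = "genome_id"
    return profile.sort_index().reindex(sorted(profile.columns), axis=1)


@dataclass
class PCAResult:
    scores: pd.DataFrame              # rows x components
    loadings: pd.DataFrame            # components x features, orthonormal
    explained_variance_ratio: np.ndarray


def pca(profiles: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """Centered PCA via SVD with a deterministic sign convention (the
    largest-magnitude loading of each component is positive)."""
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix dimensions")

    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0

    total_var = float((S ** 2).sum())
    evr = (S[:n_components] ** 2 / total_var) if total_var > 0 \
        else np.zeros(n_components)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(U[:, :n_components] * S[:n_components],
                          index=profiles.index, columns=comps)
    loadings = pd.DataFrame(Vt[:n_components], index=comps,
                            columns=profiles.columns)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=np.asarray(evr))


# ---------------------------------------------------------------------------
# core / pan genome
# ---------------------------------------------------------------------------

def core_genome(matrix: pd.DataFrame, prevalence: float = 0.95) -> list[str]:
    """Ortho-groups present (count >= 1) in at least
    ``ceil(prevalence * n_genomes)`` genomes."""
    if not 0.0 < prevalence <= 1.0:
        raise ValueError("prevalence must lie in (0, 1]")
    if matrix.empty:
        raise ValueError("empty ortho-group matrix")
    threshold = math.ceil(prevalence * matrix.shape[0])
    present = (matrix >= 1).sum(axis=0)
    return sorted(present.index[present >= threshold])


def accumulation_curve(matrix: pd.DataFrame, n_permutations: int = 100,
                       seed: int | None = None, permute: bool = True,
                       exhaustive: bool = False) -> pd.DataFrame:
    """New ortho-groups discovered per genome added.

    For each genome ordering, the count at step g is the number of groups
    first seen in the g-th genome.  With ``permute=True`` the orderings are
    ``n_permutations`` random permutations and per-step mean/sd over them
    are reported; ``exhaustive=True`` instead enumerates all n! orderings
    (small collections only); with ``permute=False`` a single pass in the
    matrix's row order is used (the order in which a planted discovery law
    holds).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    presence = (np.asarray(matrix, dtype=float) >= 1)
    n = presence.shape[0]
    if exhaustive:
        from itertools import permutations as _perms
        if n > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 genomes")
        orders = [np.array(p) for p in _perms(range(n))]
    elif not permute:
        orders = [np.arange(n)]
    else:
        orders = [np.random.default_rng(None if seed is None else [seed, p])
                  .permutation(n) for p in range(n_permutations)]

    new_counts = np.empty((len(orders), n), dtype=float)
    for i, order in enumerate(orders):
        perm = presence[order]
        any_col = perm.any(axis=0)
        first = perm[:, any_col].argmax(axis=0)
        new_counts[i] = np.bincount(first, minlength=n)

    return pd.DataFrame({
        "step": np.arange(1, n + 1),
        "mean_new": new_counts.mean(axis=0),
        "sd_new": new_counts.std(axis=0, ddof=0),
    })


@dataclass
class HeapsFit:
    kappa: float
    alpha: float
    alpha_se: float
    openness: bool  # alpha <= 1 -> open pan genome


def fit_heaps(curve: pd.DataFrame | np.ndarray) -> HeapsFit:
    """Nonlinear least-squares fit of ``n_new(g) = kappa * g**-alpha``.

    Step 1 is excluded (every gene is new by definition).  ``curve`` is
    either the frame from :func:`accumulation_curve` or a 1-D array of
    per-step mean new-group counts starting at step 1.
    """
    if isinstance(curve, pd.DataFrame):
        g = curve["step"].to_numpy(float)
        y = curve["mean_new"].to_numpy(float)
    else:
        y = np.asarray(curve, dtype=float)
        g = np.arange(1, y.size + 1, dtype=float)

    mask = g >= 2
    g, y = g[mask], y[mask]
    if g.size < 3:
        raise ValueError("Heaps fit needs at least 3 steps beyond step 1")
    if not np.any(y > 0):
        raise ValueError("degenerate accumulation curve: no new groups after step 1")

    # log-log regression start values on positive steps
    pos = y > 0
    slope, intercept = np.polyfit(np.log(g[pos]), np.log(y[pos]), 1)
    p0 = (math.exp(intercept), -slope)

    def heaps(gv, kappa, alpha):
        return kappa * gv ** (-alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(heaps, g, y, p0=p0, maxfev=20000)
    kappa, alpha = float(popt[0]), float(popt[1])
    alpha_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return HeapsFit(kappa=kappa, alpha=alpha, alpha_se=alpha_se,
                    openness=bool(alpha <= 1.0))


# ---------------------------------------------------------------------------
# distances, embedding, clustering
# ---------------------------------------------------------------------------

def binary_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Genome x genome distance on presence/absence of ortho-groups
    (Jaccard by default, Hamming as an alternative)."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genomes")
    presence = np.asarray(matrix, dtype=float) >= 1
    if not presence.any(axis=1).all():
        raise ValueError("genome with no ortho-groups present")
    if metric not in ("jaccard", "hamming"):
        raise ValueError("metric must be 'jaccard' or 'hamming'")
    d = squareform(pdist(presence, metric=metric))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def embed_2d(distances: pd.DataFrame) -> pd.DataFrame:
    """Deterministic 2-D embedding by classical (Torgerson) metric MDS.

    Double-centers the squared distances, takes the top-2 eigenpairs, and
    fixes the orientation by making the largest-magnitude coordinate of
    each axis positive.
    """
    D = np.asarray(distances, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:2]
    lams = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lams)
    for i in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, i]))
        if coords[j, i] < 0:
            coords[:, i] *= -1.0
    index = distances.index if isinstance(distances, pd.DataFrame) else None
    return pd.DataFrame(coords, index=index, columns=["mds1", "mds2"])


@dataclass
class KMeansResult:
    labels: pd.Series
    k: int
    silhouettes: dict[int, float]


def kmeans_silhouette(coords: pd.DataFrame, k_range=range(2, 11),
                      seed: int = 0, n_restarts: int = 50) -> KMeansResult:
    """k-means over ``k_range`` keeping the k with the best mean silhouette
    (ties broken toward the smallest k)."""
    X = np.asarray(coords, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range has no feasible k in [2, n-1]")

    best_k, best_sil, best_labels = None, -np.inf, None
    sils: dict[int, float] = {}
    for k in sorted(ks):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        sil = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else -1.0
        sils[k] = sil
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels

    index = coords.index if isinstance(coords, pd.DataFrame) else None
    return KMeansResult(labels=pd.Series(best_labels, index=index, name="cluster"),
                        k=int(best_k), silhouettes=sils)


# ---------------------------------------------------------------------------
# transportome
# ---------------------------------------------------------------------------

TRANSPORTER_CLASSES = ("AT", "Au", "CP", "EC", "GT", "SC", "Un")


def transportome_profile(annotations: dict[str, str],
                         detections: set[str]) -> pd.DataFrame:
    """Transporter-class shares in the genome vs the detected proteome.

    ``annotations`` maps gene id to transporter class; ``detections`` is
    the set of experimentally detected gene ids.  Both share columns sum
    to 1 (the detected column is all-NaN if nothing was detected).
    """
    if not annotations:
        raise ValueError("empty annotation table")
    ann = pd.Series(annotations, name="cls")
    genome = ann.value_counts()
    detected = ann[ann.index.isin(detections)].value_counts()
    classes = sorted(set(genome.index) | set(TRANSPORTER_CLASSES))
    out = pd.DataFrame(index=classes)
    out["genome_share"] = (genome / genome.sum()).reindex(classes).fillna(0.0)
    out["detected_share"] = ((detected / detected.sum()).reindex(classes).fillna(0.0)
                             if detected.sum() > 0 else np.nan)
    out.index.name = "transporter_class"
    return out
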