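"""Proteome pipeline for replicate peptide-count tables.

The stages mirror label-free comparative proteomics of bacterial strains
grown under many substrate conditions:

1. merge the soluble and membrane-enriched fractions per protein, keeping
   the higher peptide count;
2. require detection in at least two replicates per condition, averaging
   the merged counts of the detecting replicates;
3. call the constitutive proteome (proteins detected under every condition
   of a strain) and cross it with core-genome membership;
4. characterise per-condition abundance distributions, which are well
   described as log-normal: decade-binned histograms, fitted density mode,
   richness, per-protein log-SD variability;
5. group proteins by co-abundance across conditions and flag fold changes.

Peptide counts are semi-quantitative spectral observations; all logs are
base 10 ("one log bin" = one decade).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "merge_fractions",
    "replicate_filter",
    "DetectionResult",
    "constitutive_set",
    "categorize",
    "CATEGORIES",
    "abundance_variability",
    "VariabilityResult",
    "fit_abundance_mode",
    "AbundanceFit",
    "discrimination_diagram",
    "EllipseParams",
    "coabundance_clusters",
    "differential_flags",
    "pathway_detection_summary",
]

LN10 = np.log(10.0)

KEY_COLS = ["strain", "condition", "replicate", "protein_id"]


def merge_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Merge protein fractions by keeping the highest peptide count per
    (strain, condition, replicate, protein).  Idempotent: a table without
    a fraction column is returned unchanged (copy)."""
    if "fraction" not in table.columns:
        return table.copy()
    if (table["peptide_count"] < 1).any():
        raise ValueError("peptide counts must be >= 1")
    merged = (table.groupby(KEY_COLS, as_index=False, sort=True)
              ["peptide_count"].max())
    return merged


@dataclass
class DetectionResult:
    """Per-strain detection matrices plus count bookkeeping.

    ``matrices`` maps strain -> proteins x conditions frame of merged
    abundances (mean over detecting replicates; 0 = not detected after the
    replicate filter).  Raw peptide counts are never silently lost:
    ``kept_counts + dropped_counts`` equals the merged table's total.
    """

    matrices: dict[str, pd.DataFrame]
    kept_counts: int
    dropped_counts: int
    dropped_conditions: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, strain: str) -> pd.DataFrame:
        return self.matrices[strain]

    def strains(self) -> list[str]:
        return sorted(self.matrices)


def replicate_filter(merged: pd.DataFrame, min_reps: int = 2) -> DetectionResult:
    """Keep detections supported by at least ``min_reps`` replicates.

    A protein counts as detected in (strain, condition) iff it appears in
    >= min_reps replicates there; its abundance is the mean merged count
    over the detecting replicates, otherwise 0.  Conditions whose design
    has fewer than min_reps replicates are dropped with a warning.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    if "fraction" in merged.columns:
        raise ValueError("run merge_fractions first (fraction column present)")

    design = merged.groupby(["strain", "condition"])["replicate"].nunique()
    bad = design[design < min_reps]
    dropped_conditions = [tuple(ix) for ix in bad.index]
    if dropped_conditions:
        warnings.warn(
            f"dropping {len(dropped_conditions)} condition(s) with fewer than "
            f"{min_reps} replicates: {dropped_conditions}")
        keep = ~merged.set_index(["strain", "condition"]).index.isin(bad.index)
        merged = merged.loc[np.asarray(keep)]

    stats_df = (merged.groupby(["strain", "condition", "protein_id"])
                ["peptide_count"].agg(n_reps="size", mean="mean", total="sum")
                .reset_index())
    detected = stats_df["n_reps"] >= min_reps
    kept = int(stats_df.loc[detected, "total"].sum())
    total = int(merged["peptide_count"].sum())

    matrices: dict[str, pd.DataFrame] = {}
    for strain, grp in stats_df[detected].groupby("strain"):
        mat = grp.pivot(index="protein_id", columns="condition",
                        values="mean").fillna(0.0)
        all_conds = sorted(merged.loc[merged["strain"] == strain,
                                      "condition"].unique())
        matrices[strain] = mat.reindex(columns=all_conds, fill_value=0.0).sort_index()

    return DetectionResult(matrices=matrices, kept_counts=kept,
                           dropped_counts=total - kept,
                           dropped_conditions=dropped_conditions)


def constitutive_set(dm: DetectionResult | dict[str, pd.DataFrame]
                     ) -> dict[str, set[str]]:
    """Constitutive proteome per strain: proteins detected under every
    condition of that strain."""
    matrices = dm.matrices if isinstance(dm, DetectionResult) else dm
    out: dict[str, set[str]] = {}
    for strain, mat in matrices.items():
        if mat.shape[1] < 1:
            raise ValueError(f"strain {strain} has no conditions")
        out[strain] = set(mat.index[(mat > 0).all(axis=1)])
    return out


CATEGORIES = (
    "core_constitutive",
    "core_nonconstitutive",
    "noncore_constitutive",
    "noncore_nonconstitutive",
)


def categorize(dm: DetectionResult | dict[str, pd.DataFrame],
               constitutive: dict[str, set[str]],
               core_encoded: dict[str, set[str]] | set[str]) -> pd.DataFrame:
    """2x2 classification of detected proteins: core-gene encoded (or not)
    x constitutively formed (or not), with per-category protein counts and
    peptide-count shares (shares sum to 1 per strain)."""
    matrices = dm.matrices if isinstance(dm, DetectionResult) else dm
    rows = []
    for strain, mat in sorted(matrices.items()):
        core = core_encoded[strain] if isinstance(core_encoded, dict) \
            else core_encoded
        const = constitutive.get(strain, set())
        abund = mat.sum(axis=1)
        total = float(abund.sum())
        for cat in CATEGORIES:
            want_core = cat.startswith("core")
            want_const = cat.endswith("_constitutive") and "non" not in cat.split("_")[1]
            sel = [p for p in mat.index
                   if (p in core) == want_core and (p in const) == want_const]
            rows.append({
                "strain": strain,
                "category": cat,
                "n_proteins": len(sel),
                "peptide_count_share": (float(abund.loc[sel].sum()) / total
                                        if total > 0 else 0.0),
            })
    return pd.DataFrame(rows)


@dataclass
class VariabilityResult:
    log_sd: pd.Series       # per-protein SD of log10 abundance (>=2 conditions)
    cdf_grid: np.ndarray
    cdf_values: np.ndarray  # kernel-smoothed cdf over proteins
    n_excluded: int         # proteins detected in < 2 conditions


def abundance_variability(matrix: pd.DataFrame,
                          grid_points: int = 200) -> VariabilityResult:
    """Per-protein log10-abundance SD across detected conditions, with a
    Gaussian-kernel-smoothed cdf (Silverman bandwidth) over proteins.

    Proteins detected in fewer than 2 conditions carry no SD; they are
    excluded and counted.
    """
    sds: dict[str, float] = {}
    n_excluded = 0
    for pid, row in matrix.iterrows():
        vals = row[row > 0].to_numpy(float)
        if vals.size < 2:
            n_excluded += 1
            continue
        sds[pid] = float(np.std(np.log10(vals), ddof=1))
    log_sd = pd.Series(sds, name="log_sd", dtype=float)

    if log_sd.empty:
        return VariabilityResult(log_sd, np.array([]), np.array([]), n_excluded)
    x = log_sd.to_numpy()
    lo, hi = x.min(), x.max()
    pad = 0.1 * max(hi - lo, 1e-6)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    if np.ptp(x) > 0:
        kde = stats.gaussian_kde(x, bw_method="silverman")
        cdf = np.array([kde.integrate_box_1d(-np.inf, g) for g in grid])
        cdf = np.clip(cdf, 0.0, 1.0)
    else:
        cdf = (grid >= x[0]).astype(float)  # degenerate: step function
    return VariabilityResult(log_sd, grid, cdf, n_excluded)


@dataclass
class AbundanceFit:
    strain: str
    condition: str
    richness: int                 # number of detected proteins
    fitted: bool
    mu: float = np.nan            # mean of log10 abundance
    sigma: float = np.nan         # SD of log10 abundance
    mode: float = np.nan          # fitted log-normal density peak (count scale)
    bin_mode: float = np.nan      # geometric centre of the tallest decade bin
    hist_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_counts: np.ndarray = field(default_factory=lambda: np.array([]))


def fit_abundance_mode(dm: DetectionResult | dict[str, pd.DataFrame],
                       strain: str, condition: str,
                       min_proteins: int = 10) -> AbundanceFit:
    """Log-normal characterisation of one strain x condition abundance
    distribution: decade-binned histogram, fitted density mode and richness.

    The log-normal is fitted by moments of log10 abundance; its density
    peak on the count scale is ``10**(mu - sigma**2 * ln 10)``.  With fewer
    than ``min_proteins`` detected proteins the fit is refused but richness
    is still reported.
    """
    matrices = dm.matrices if isinstance(dm, DetectionResult) else dm
    col = matrices[strain][condition]
    abund = col[col > 0].to_numpy(float)
    richness = int(abund.size)
    if richness < min_proteins:
        return AbundanceFit(strain=strain, condition=condition,
                            richness=richness, fitted=False)

    logs = np.log10(abund)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    mode = float(10.0 ** (mu - sigma ** 2 * LN10))

    lo = int(np.floor(logs.min()))
    hi = int(np.ceil(logs.max()))
    if hi <= lo:
        hi = lo + 1
    edges = 10.0 ** np.arange(lo, hi + 1)        # decade bins (log bin size 1)
    counts, _ = np.histogram(abund, bins=edges)
    ibest = int(np.argmax(counts))
    bin_mode = float(np.sqrt(edges[ibest] * edges[ibest + 1]))

    return AbundanceFit(strain=strain, condition=condition, richness=richness,
                        fitted=True, mu=mu, sigma=sigma, mode=mode,
                        bin_mode=bin_mode, hist_edges=edges, hist_counts=counts)


@dataclass
class EllipseParams:
    strain: str
    center: tuple[float, float]       # (mean richness, mean log10 mode)
    axes: tuple[float, float]         # 2*sqrt(eigenvalue), major then minor
    orientation: float                # radians of the major eigenvector
    degenerate: bool                  # collinear points (zero minor axis)


def discrimination_diagram(fits: list[AbundanceFit]) -> dict[str, EllipseParams]:
    """Per-strain covariance ellipses in the (richness, log10 mode) plane,
    from the eigendecomposition of the point cloud (axes = mean +- 2 sd
    along each eigenvector)."""
    by_strain: dict[str, list[AbundanceFit]] = {}
    for f in fits:
        if f.fitted:
            by_strain.setdefault(f.strain, []).append(f)

    out: dict[str, EllipseParams] = {}
    for strain, flist in sorted(by_strain.items()):
        if len(flist) < 3:
            raise ValueError(f"strain {strain} has < 3 fitted conditions")
        pts = np.array([[f.richness, np.log10(f.mode)] for f in flist])
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        major = eigvecs[:, order[0]]
        out[strain] = EllipseParams(
            strain=strain,
            center=(float(center[0]), float(center[1])),
            axes=(2.0 * float(np.sqrt(eigvals[0])),
                  2.0 * float(np.sqrt(eigvals[1]))),
            orientation=float(np.arctan2(major[1], major[0])),
            degenerate=bool(eigvals[1] <= 1e-12 * max(eigvals[0], 1.0)),
        )
    return out


def coabundance_clusters(dm: DetectionResult | dict[str, pd.DataFrame],
                         strain: str, cut_height: float = 0.5) -> list[list[str]]:
    """Group proteins by similarity of their abundance patterns across
    conditions: average-linkage hierarchical clustering under correlation
    distance (1 - Pearson on log10(abundance + 1) profiles), tree cut at
    ``cut_height``; groups are reported largest first.

    Proteins detected in < 2 conditions are excluded; proteins with a flat
    (zero-variance) profile cannot be correlated and form one trailing
    group per distinct profile.
    """
    matrices = dm.matrices if isinstance(dm, DetectionResult) else dm
    mat = matrices[strain]
    mat = mat[(mat > 0).sum(axis=1) >= 2]
    if mat.empty:
        return []
    profiles = np.log10(mat.to_numpy(float) + 1.0)
    ids = list(mat.index)

    variable = profiles.std(axis=1) > 0
    groups: list[list[str]] = []
    if variable.sum() == 1:
        groups.append([ids[int(np.flatnonzero(variable)[0])]])
    elif variable.sum() > 1:
        sub = profiles[variable]
        sub_ids = [i for i, v in zip(ids, variable) if v]
        Z = linkage(sub, method="average", metric="correlation")
        labels = fcluster(Z, t=cut_height, criterion="distance")
        for lab in np.unique(labels):
            groups.append([sub_ids[i] for i in np.flatnonzero(labels == lab)])

    flat_ids = [i for i, v in zip(ids, variable) if not v]
    if flat_ids:
        flat_profiles: dict[tuple, list[str]] = {}
        for i in flat_ids:
            key = tuple(np.round(profiles[ids.index(i)], 12))
            flat_profiles.setdefault(key, []).append(i)
        groups.extend(flat_profiles.values())

    return sorted(groups, key=lambda g: (-len(g), g[0]))


def differential_flags(dm: DetectionResult | dict[str, pd.DataFrame],
                       strain: str, test_condition: str,
                       reference_condition: str,
                       threshold: float = 1.5) -> pd.DataFrame:
    """Fold-change flags between two conditions: a protein is significant
    iff its abundance ratio is >= threshold or <= 1/threshold; proteins
    detected on only one side are reported qualitatively as on/off, and
    proteins absent on both sides are excluded."""
    if threshold < 1.0:
        raise ValueError("threshold must be >= 1")
    matrices = dm.matrices if isinstance(dm, DetectionResult) else dm
    mat = matrices[strain]
    for cond in (test_condition, reference_condition):
        if cond not in mat.columns:
            raise ValueError(f"condition {cond!r} absent for strain {strain}")

    test, ref = mat[test_condition], mat[reference_condition]
    rows = []
    for pid in mat.index:
        t, r = float(test[pid]), float(ref[pid])
        if t == 0 and r == 0:
            continue
        if t > 0 and r > 0:
            ratio = t / r
            if ratio >= threshold:
                status = "up"
            elif ratio <= 1.0 / threshold:
                status = "down"
            else:
                status = "unchanged"
            flagged = status in ("up", "down")
        else:
            ratio = np.nan
            status = "on" if t > 0 else "off"
            flagged = True
        rows.append({"protein_id": pid, "test_abundance": t,
                     "reference_abundance": r, "ratio": ratio,
                     "status": status, "flagged": flagged})
    return pd.DataFrame(rows, columns=["protein_id", "test_abundance",
                                       "reference_abundance", "ratio",
                                       "status", "flagged"])


def pathway_detection_summary(pathways: pd.DataFrame,
                              dm: DetectionResult | dict[str, pd.DataFrame]
                              ) -> pd.DataFrame:
    """Detected / total member proteins per (pathway, strain).

    ``pathways`` has columns pathway_id, strain, protein_id.  A member is
    detected iff present (any condition) in that strain's detection
    matrix; member ids never detected in the proteome trigger one summary
    warning.  (pathway, strain) pairs without membership rows are emitted
    with ``present=False`` (genes absent), a minus in the study's figures.
    """
    required = {"pathway_id", "strain", "protein_id"}
    if missing := required - set(pathways.columns):
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    matrices = dm.matrices if isinstance(dm, DetectionResult) else dm

    unknown = 0
    rows = []
    all_pathways = sorted(pathways["pathway_id"].unique())
    all_strains = sorted(set(pathways["strain"]).union(matrices))
    grouped = pathways.groupby(["pathway_id", "strain"])["protein_id"]
    members_map = {k: sorted(set(v)) for k, v in grouped}

    for pw in all_pathways:
        for strain in all_strains:
            members = members_map.get((pw, strain))
            if not members:
                rows.append({"pathway_id": pw, "strain": strain, "present": False,
                             "n_members": 0, "n_detected": 0,
                             "detected_fraction": np.nan})
                continue
            mat = matrices.get(strain)
            detected = 0
            for pid in members:
                if mat is not None and pid in mat.index:
                    if (mat.loc[pid] > 0).any():
                        detected += 1
                else:
                    unknown += 1
            rows.append({"pathway_id": pw, "strain": strain, "present": True,
                         "n_members": len(members), "n_detected": detected,
                         "detected_fraction": detected / len(members)})
    if unknown:
        warnings.warn(f"{unknown} pathway member protein id(s) never detected "
                      "in the corresponding proteome")
    return pd.DataFrame(rows)
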