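"""Synthetic data generators emulating the statistical structure of a
comparative proteogenomic study of sulfate-reducing bacteria.

Four independent generators produce the inputs the analysis modules consume,
each with planted ground truth for recovery testing:

* georeferenced occurrence records drawn around well-separated cluster
  centres (for density-based biogeographic clustering);
* genomes x ortho-group count matrices with a core / shell / cloud
  architecture whose per-genome novel-gene counts follow a power law
  (for pan-genome openness analytics);
* long-format replicate peptide-count tables with log-normal latent
  abundances, a planted constitutive protein subset and substrate-specific
  modules (for the proteome pipeline);
* diverged protein families with a known number of substitutions per
  homolog (for profile / delta-bitscore conservation screening).

All generators are deterministic given ``SimulationConfig.seed``: each block
draws from its own ``numpy`` Generator seeded from ``(block_id, seed)``, so
toggling one generator never perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SiteConfig",
    "PangenomeConfig",
    "ProteomeConfig",
    "FamilyConfig",
    "SimulationConfig",
    "simulate_occurrences",
    "simulate_pangenome",
    "simulate_proteome_counts",
    "simulate_protein_family",
    "simulate_all",
    "write_occurrences",
    "read_occurrences",
    "write_ortho_matrix",
    "read_ortho_matrix",
    "write_peptide_counts",
    "read_peptide_counts",
    "write_fasta",
    "read_fasta",
    "write_ground_truth",
]

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed sub-seed ids per generator block
_BLOCK_SITES = 11
_BLOCK_PANGENOME = 23
_BLOCK_PROTEOME = 37
_BLOCK_FAMILY = 53


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configuration blocks
# ---------------------------------------------------------------------------

def _default_genus_weights() -> dict[str, float]:
    # relative detection frequencies of the five focal genera; the
    # Desulfosarcina/Desulfococcus group dominates field surveys
    return {
        "Desulfosarcina/Desulfococcus": 0.60,
        "Desulfonema": 0.15,
        "Desulfobacterium": 0.15,
        "Desulfobacula": 0.10,
    }


def _default_habitat_weights() -> dict[str, float]:
    return {
        "marine deep sea": 0.35,
        "marine shelf": 0.30,
        "brackish/freshwater": 0.20,
        "other": 0.15,
    }


def _default_physicochemical() -> dict[str, tuple[float, float]]:
    # plausible ranges for anoxic marine sediments (units: mM, PSU, uM, degC)
    return {
        "sulfate_mM": (0.0, 30.0),
        "salinity": (0.0, 40.0),
        "oxygen": (0.0, 5.0),
        "temperature_C": (-2.0, 40.0),
    }


@dataclass
class SiteConfig:
    """Clustered georeferenced occurrence records.

    Sites are drawn around ``n_clusters`` centres placed at least
    ``min_separation_km`` apart (great circle), each site offset from its
    centre on a local tangent plane by at most ``spread_km``; a second
    genus record is added at a site with probability
    ``multi_occurrence_prob`` so that occurrences outnumber sites, as in
    literature surveys.
    """

    n_clusters: int = 30
    sites_per_cluster: int = 17
    spread_km: float = 50.0
    min_separation_km: float = 1500.0
    lat_range: tuple[float, float] = (-60.0, 70.0)
    genus_weights: dict[str, float] = field(default_factory=_default_genus_weights)
    habitat_weights: dict[str, float] = field(default_factory=_default_habitat_weights)
    physicochemical: dict[str, tuple[float, float]] = field(
        default_factory=_default_physicochemical
    )
    multi_occurrence_prob: float = 0.30
    missing_value_prob: float = 0.20
    missing_habitat_prob: float = 0.05

    def validate(self) -> None:
        if self.n_clusters < 1 or self.sites_per_cluster < 1:
            raise ConfigError("n_clusters and sites_per_cluster must be >= 1")
        if self.spread_km < 0:
            raise ConfigError("spread_km must be >= 0")
        for name, weights in (("genus", self.genus_weights),
                              ("habitat", self.habitat_weights)):
            if not weights:
                raise ConfigError(f"{name}_weights must be non-empty")
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{name}_weights must be non-negative")
            if sum(weights.values()) <= 0:
                raise ConfigError(f"{name}_weights must sum to > 0")
        for p in (self.multi_occurrence_prob, self.missing_value_prob,
                  self.missing_habitat_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")


@dataclass
class PangenomeConfig:
    """Core / shell / cloud ortho-group architecture.

    ``core_size`` groups are present in every genome; each of ``shell_size``
    groups is carried per genome with probability ``shell_prob``; the g-th
    genome additionally gains ``Poisson(cloud_kappa * g**-cloud_alpha)``
    novel singleton groups, so new-gene discovery decays as a power law in
    generation order.
    """

    n_genomes: int = 43
    core_size: int = 713
    shell_size: int = 2000
    shell_prob: float = 0.30
    cloud_kappa: float = 500.0
    cloud_alpha: float = 0.9

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        if self.core_size < 0 or self.shell_size < 0:
            raise ConfigError("core_size and shell_size must be >= 0")
        if not 0.0 <= self.shell_prob <= 1.0:
            raise ConfigError("shell_prob must lie in [0, 1]")
        if self.cloud_kappa < 0:
            raise ConfigError("cloud_kappa must be >= 0")
        if self.cloud_alpha <= 0:
            raise ConfigError("cloud_alpha must be > 0")


@dataclass
class ProteomeConfig:
    """Replicate peptide-count tables with a planted constitutive subset.

    Each protein carries a latent abundance ``exp(N(lognormal_mu,
    lognormal_sigma**2))`` (natural-log parameters; the default median of
    ~20 peptide counts matches semi-quantitative shotgun data).
    Constitutive proteins are expressed under every condition; the
    remaining proteins belong to substrate modules active under proper
    subsets of the conditions.  Replicate counts are Poisson around the
    latent abundance, split across a soluble and a membrane fraction.
    Under ``detection_dropout_rule="poisson_zero"`` a protein is missed in
    a replicate iff its Poisson draw is zero; ``"none"`` clamps the primary
    fraction count to >= 1 so every active protein is always detected.
    """

    strains: tuple[str, ...] = ("Dsv", "Dcm", "Dnl", "Dnm", "Dbt", "Dta")
    conditions_per_strain: int = 8
    replicates: int = 3
    fractions: tuple[str, ...] = ("soluble", "membrane")
    n_proteins: int = 1000
    constitutive_fraction: float = 0.25
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.0
    detection_dropout_rule: str = "poisson_zero"  # or "none"
    max_module_conditions: int = 3
    membrane_protein_prob: float = 0.30
    secondary_fraction_factor: float = 0.25

    def validate(self) -> None:
        if not self.strains:
            raise ConfigError("at least one strain required")
        if self.conditions_per_strain < 1 or self.replicates < 1:
            raise ConfigError("conditions_per_strain and replicates must be >= 1")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 0.0 <= self.constitutive_fraction <= 1.0:
            raise ConfigError("constitutive_fraction must lie in [0, 1]")
        if self.lognormal_sigma < 0:
            raise ConfigError("lognormal_sigma must be >= 0")
        if self.detection_dropout_rule not in ("poisson_zero", "none"):
            raise ConfigError("detection_dropout_rule must be 'poisson_zero' or 'none'")
        if not self.fractions:
            raise ConfigError("at least one fraction required")
        if not 0.0 <= self.membrane_protein_prob <= 1.0:
            raise ConfigError("membrane_protein_prob must lie in [0, 1]")


@dataclass
class FamilyConfig:
    """Diverged protein family with a known substitution count per homolog."""

    ancestor_length: int = 200
    n_homologs: int = 12
    substitutions_per_seq: int = 10

    def validate(self) -> None:
        if self.ancestor_length < 10:
            raise ConfigError("ancestor_length must be >= 10")
        if self.n_homologs < 1:
            raise ConfigError("n_homologs must be >= 1")
        if self.substitutions_per_seq < 0:
            raise ConfigError("substitutions_per_seq must be >= 0")
        if self.substitutions_per_seq > self.ancestor_length:
            raise ConfigError("substitutions_per_seq cannot exceed ancestor_length")


@dataclass
class SimulationConfig:
    seed: int = 0
    sites: SiteConfig = field(default_factory=SiteConfig)
    pangenome: PangenomeConfig = field(default_factory=PangenomeConfig)
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)
    family: FamilyConfig = field(default_factory=FamilyConfig)

    def validate(self) -> None:
        self.sites.validate()
        self.pangenome.validate()
        self.proteome.validate()
        self.family.validate()

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(seed=raw.get("seed", 0))
        for block, klass in (("sites", SiteConfig), ("pangenome", PangenomeConfig),
                             ("proteome", ProteomeConfig), ("family", FamilyConfig)):
            if block in raw:
                params = dict(raw[block])
                for key, val in params.items():
                    if isinstance(val, list):
                        params[key] = tuple(val)
                setattr(cfg, block, klass(**params))
        cfg.validate()
        return cfg


def _rng(cfg: SimulationConfig, block: int) -> np.random.Generator:
    return np.random.default_rng([block, cfg.seed])


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float],
                     size: int) -> np.ndarray:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=p)


# ---------------------------------------------------------------------------
# occurrence records
# ---------------------------------------------------------------------------

def simulate_occurrences(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Draw clustered occurrence records.

    Returns ``(table, ground_truth)``; the table carries one row per
    occurrence with columns site_id, latitude, longitude, genus, habitat,
    the physicochemical parameters, and the planted ``true_cluster`` label.
    """
    cfg.validate()
    sc = cfg.sites
    rng = _rng(cfg, _BLOCK_SITES)

    centers = _draw_cluster_centers(rng, sc)
    rows = []
    site_idx = 0
    for ci, (clat, clon) in enumerate(centers):
        for _ in range(sc.sites_per_cluster):
            # uniform offset on the local tangent plane within spread_km
            r = sc.spread_km * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            dlat = (r * math.sin(theta)) / KM_PER_DEG
            coslat = max(math.cos(math.radians(clat)), 1e-6)
            dlon = (r * math.cos(theta)) / (KM_PER_DEG * coslat)
            lat = float(np.clip(clat + dlat, -90.0, 90.0))
            lon = ((clon + dlon + 180.0) % 360.0) - 180.0
            site_id = f"site_{site_idx:04d}"
            site_idx += 1
            n_occ = 2 if rng.uniform() < sc.multi_occurrence_prob else 1
            for _ in range(n_occ):
                rows.append(_draw_record(rng, sc, site_id, lat, lon, ci))

    table = pd.DataFrame(rows)
    truth = {
        "n_clusters": sc.n_clusters,
        "centers": [[float(a), float(b)] for a, b in centers],
        "spread_km": sc.spread_km,
    }
    return table, truth


def _draw_cluster_centers(rng: np.random.Generator,
                          sc: SiteConfig) -> list[tuple[float, float]]:
    from .biogeography import great_circle_distance

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < sc.n_clusters:
        attempts += 1
        if attempts > 10000 * sc.n_clusters:
            raise ConfigError(
                "could not place cluster centers with the requested separation"
            )
        lat = rng.uniform(*sc.lat_range)
        lon = rng.uniform(-180.0, 180.0)
        if all(great_circle_distance((lat, lon), c) >= sc.min_separation_km
               for c in centers):
            centers.append((lat, lon))
    return centers


def _draw_record(rng: np.random.Generator, sc: SiteConfig, site_id: str,
                 lat: float, lon: float, cluster: int) -> dict:
    rec = {
        "site_id": site_id,
        "latitude": lat,
        "longitude": lon,
        "genus": str(_weighted_choice(rng, sc.genus_weights, 1)[0]),
        "habitat": (np.nan if rng.uniform() < sc.missing_habitat_prob
                    else str(_weighted_choice(rng, sc.habitat_weights, 1)[0])),
        "true_cluster": cluster,
    }
    for param, (lo, hi) in sorted(sc.physicochemical.items()):
        rec[param] = (np.nan if rng.uniform() < sc.missing_value_prob
                      else float(rng.uniform(lo, hi)))
    return rec


# ---------------------------------------------------------------------------
# pan-genome matrix
# ---------------------------------------------------------------------------

def simulate_pangenome(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a genomes x ortho-groups count matrix with planted structure.

    Returns ``(matrix, ground_truth)`` where the matrix has genomes as rows
    (in generation order, the order in which the planted power law holds)
    and ortho-groups as columns; ground truth records the core group ids
    and the cloud power-law parameters.
    """
    cfg.validate()
    pc = cfg.pangenome
    rng = _rng(cfg, _BLOCK_PANGENOME)

    genomes = [f"genome_{g + 1:03d}" for g in range(pc.n_genomes)]
    blocks: list[pd.DataFrame] = []

    core_ids = [f"core_{i + 1:05d}" for i in range(pc.core_size)]
    if core_ids:
        blocks.append(pd.DataFrame(1, index=genomes, columns=core_ids, dtype=int))

    if pc.shell_size:
        shell = (rng.uniform(size=(pc.n_genomes, pc.shell_size))
                 < pc.shell_prob).astype(int)
        shell_ids = [f"shell_{i + 1:05d}" for i in range(pc.shell_size)]
        shell_df = pd.DataFrame(shell, index=genomes, columns=shell_ids)
        shell_df = shell_df.loc[:, shell_df.sum(axis=0) > 0]  # drop unrealised groups
        blocks.append(shell_df)

    cloud_counts = []
    cloud_cols: dict[str, np.ndarray] = {}
    for g in range(1, pc.n_genomes + 1):
        lam = pc.cloud_kappa * g ** (-pc.cloud_alpha)
        n_new = int(rng.poisson(lam)) if lam > 0 else 0
        cloud_counts.append(n_new)
        for i in range(n_new):
            col = np.zeros(pc.n_genomes, dtype=int)
            col[g - 1] = 1
            cloud_cols[f"cloud_g{g:03d}_{i + 1:04d}"] = col
    if cloud_cols:
        blocks.append(pd.DataFrame(cloud_cols, index=genomes))

    matrix = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=genomes)
    matrix.index.name = "genome"
    truth = {
        "core_groups": core_ids,
        "cloud_alpha": pc.cloud_alpha,
        "cloud_kappa": pc.cloud_kappa,
        "cloud_new_per_genome": cloud_counts,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# replicate peptide counts
# ---------------------------------------------------------------------------

def simulate_proteome_counts(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a long-format replicate peptide-count table.

    Returns ``(table, ground_truth)``; the table has columns strain,
    condition, replicate, fraction, protein_id, peptide_count (rows only
    where a count was observed, counts >= 1); ground truth records the
    planted constitutive set and module -> condition map per strain.
    """
    cfg.validate()
    pr = cfg.proteome
    rng = _rng(cfg, _BLOCK_PROTEOME)

    rows: list[tuple] = []
    constitutive: dict[str, list[str]] = {}
    modules: dict[str, dict[str, list[str]]] = {}

    conditions = [f"cond_{c + 1:02d}" for c in range(pr.conditions_per_strain)]
    n_const = int(round(pr.constitutive_fraction * pr.n_proteins))

    for strain in pr.strains:
        prot_ids = [f"{strain}_p{i + 1:05d}" for i in range(pr.n_proteins)]
        constitutive[strain] = prot_ids[:n_const]
        strain_modules: dict[str, list[str]] = {}

        latent = np.exp(rng.normal(pr.lognormal_mu, pr.lognormal_sigma,
                                   size=pr.n_proteins))
        is_membrane = rng.uniform(size=pr.n_proteins) < pr.membrane_protein_prob

        # assign non-constitutive proteins to substrate modules active under
        # proper subsets of the conditions (1 .. max_module_conditions)
        active: dict[str, list[str]] = {}
        for pi in range(pr.n_proteins):
            pid = prot_ids[pi]
            if pi < n_const:
                active[pid] = conditions
            else:
                max_k = min(pr.max_module_conditions,
                            max(1, pr.conditions_per_strain - 1))
                k = int(rng.integers(1, max_k + 1))
                conds = sorted(rng.choice(len(conditions), size=k, replace=False))
                active[pid] = [conditions[c] for c in conds]
                strain_modules[pid] = active[pid]

        for pi, pid in enumerate(prot_ids):
            primary = pr.fractions[-1] if is_membrane[pi] else pr.fractions[0]
            for cond in active[pid]:
                for rep in range(1, pr.replicates + 1):
                    for frac in pr.fractions:
                        lam = latent[pi] if frac == primary \
                            else latent[pi] * pr.secondary_fraction_factor
                        count = int(rng.poisson(lam))
                        if (pr.detection_dropout_rule == "none"
                                and frac == primary):
                            count = max(count, 1)
                        if count >= 1:
                            rows.append((strain, cond, rep, frac, pid, count))
        modules[strain] = strain_modules

    table = pd.DataFrame(
        rows,
        columns=["strain", "condition", "replicate", "fraction",
                 "protein_id", "peptide_count"],
    )
    truth = {
        "constitutive": constitutive,
        "modules": modules,
        "lognormal_mu": pr.lognormal_mu,
        "lognormal_sigma": pr.lognormal_sigma,
        "conditions": conditions,
    }
    return table, truth


# ---------------------------------------------------------------------------
# diverged protein family
# ---------------------------------------------------------------------------

def simulate_protein_family(
    cfg: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict]:
    """Derive homologs from a random ancestor by point substitutions.

    Returns ``(msa, sequences, ground_truth)``.  The alignment is the
    trivial ungapped one (ancestor first), so msa and sequences carry the
    same residues; ground truth records the substituted positions per
    homolog (0-based).
    """
    cfg.validate()
    fc = cfg.family
    rng = _rng(cfg, _BLOCK_FAMILY)

    aa = np.array(list(AMINO_ACIDS))
    ancestor = "".join(rng.choice(aa, size=fc.ancestor_length))

    records = [("ancestor", ancestor)]
    substitutions: dict[str, list[int]] = {"ancestor": []}
    for h in range(1, fc.n_homologs + 1):
        name = f"hom_{h:03d}"
        seq = list(ancestor)
        pos = sorted(rng.choice(fc.ancestor_length,
                                size=fc.substitutions_per_seq, replace=False))
        for p in pos:
            alternatives = [a for a in AMINO_ACIDS if a != seq[p]]
            seq[p] = alternatives[int(rng.integers(len(alternatives)))]
        records.append((name, "".join(seq)))
        substitutions[name] = [int(p) for p in pos]

    truth = {
        "ancestor": ancestor,
        "substitutions": substitutions,
        "substitutions_per_seq": fc.substitutions_per_seq,
    }
    return records, list(records), truth


# ---------------------------------------------------------------------------
# readers / writers (plain-text formats, lossless round trips)
# ---------------------------------------------------------------------------

def write_occurrences(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_occurrences(path: str | Path, dedupe_coords: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    if dedupe_coords:
        df = df.drop_duplicates(subset=["latitude", "longitude", "genus"])
    return df


def write_ortho_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome")


def read_ortho_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome")


def write_peptide_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_peptide_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> None:
    """Run every generator and write tables, FASTAs and truth sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    occ, occ_truth = simulate_occurrences(cfg)
    write_occurrences(occ, out / "occurrences.csv")
    write_ground_truth(occ_truth, out / "occurrences.truth.json")

    matrix, pg_truth = simulate_pangenome(cfg)
    write_ortho_matrix(matrix, out / "ortho_groups.tsv")
    write_ground_truth(pg_truth, out / "ortho_groups.truth.json")

    counts, prot_truth = simulate_proteome_counts(cfg)
    write_peptide_counts(counts, out / "peptide_counts.tsv")
    write_ground_truth(prot_truth, out / "peptide_counts.truth.json")

    msa, seqs, fam_truth = simulate_protein_family(cfg)
    write_fasta(msa, out / "family.aln.faa")
    write_fasta(seqs, out / "family.faa")
    write_ground_truth(fam_truth, out / "family.truth.json")

    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=1, default=list))
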