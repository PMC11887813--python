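"""Profile-based conservation screening of catabolic genes.

A seed multiple alignment is converted to a position-specific log-odds
profile (scores in bits against a background amino-acid distribution).
Sequences are scored by optimal global alignment to the profile with
affine gap penalties (Gotoh), and conservation is expressed as the delta
bitscore: reference-sequence bitscore minus query bitscore for the same
profile, i.e. 0 for the reference and increasingly positive for more
diverged homologs.  A separate scanner locates palindromic operator
motifs (a k-mer equal to its own reverse complement) within a fixed
window upstream of a reference point, as used for TetR-type repressor
sites ~20-40 bp upstream of a transcription start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ProfileModel",
    "build_profile",
    "score_sequence",
    "HitRecord",
    "delta_bitscore",
    "screen_gene_sets",
    "conservation_heatmap",
    "find_palindromic_operators",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_GAP_CHARS = {"-", "."}

DEFAULT_GAP_OPEN = 11.0    # bits
DEFAULT_GAP_EXTEND = 1.0   # bits


@dataclass
class ProfileModel:
    """Position-specific log-odds scores (bits) over the 20 amino acids."""

    name: str
    scores: np.ndarray               # (n_columns, 20)
    background: np.ndarray           # (20,), sums to 1
    pseudocount: float
    n_dropped_columns: int = 0
    kept_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (n_columns, 20)")
        if self.scores.shape[0] < 1:
            raise ValueError("profile needs at least one column")
        if not np.isfinite(self.scores).all():
            raise ValueError("profile scores must be finite")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.scores.argmax(axis=1))


def build_profile(msa: list[tuple[str, str]], pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  name: str = "profile",
                  max_gap_fraction: float = 0.5) -> ProfileModel:
    """Build a log-odds profile from an aligned protein family.

    Columns with more than ``max_gap_fraction`` gaps are dropped (their
    count is reported on the model).  Per kept column,

        score(a) = log2( (count_a + pc * bg_a) / (n_eff + pc) / bg_a )

    where n_eff is the number of non-gap residues in the column.
    """
    if len(msa) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lengths = {len(seq) for _, seq in msa}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    length = lengths.pop()
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)

    seqs = [seq.upper() for _, seq in msa]
    cols: list[np.ndarray] = []
    kept: list[int] = []
    dropped = 0
    for j in range(length):
        residues = [s[j] for s in seqs]
        gaps = sum(r in _GAP_CHARS for r in residues)
        if gaps / len(residues) > max_gap_fraction:
            dropped += 1
            continue
        counts = np.zeros(20)
        for r in residues:
            if r in _GAP_CHARS:
                continue
            if r not in _AA_INDEX:
                raise ValueError(f"illegal residue {r!r} in alignment column {j}")
            counts[_AA_INDEX[r]] += 1.0
        n_eff = counts.sum()
        probs = (counts + pseudocount * background) / (n_eff + pseudocount)
        cols.append(np.log2(probs / background))
        kept.append(j)
    if not cols:
        raise ValueError("all alignment columns were gap-dropped")
    return ProfileModel(name=name, scores=np.vstack(cols),
                        background=background, pseudocount=pseudocount,
                        n_dropped_columns=dropped, kept_columns=kept)


def _encode(seq: str, unknown_residue: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=int)
    for i, r in enumerate(seq.upper()):
        if r in _AA_INDEX:
            idx[i] = _AA_INDEX[r]
        elif unknown_residue == "neutral":
            idx[i] = -1   # scores 0 against every column
        else:
            raise ValueError(f"illegal residue {r!r} in sequence")
    return idx


def score_sequence(profile: ProfileModel, seq: str,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   unknown_residue: str = "error") -> float:
    """Bitscore of the optimal global (Gotoh affine-gap) alignment of a
    protein sequence to the profile columns.

    Match scores are the per-column log-odds; gaps cost ``gap_open`` bits
    to open and ``gap_extend`` bits per further position.  Deterministic.
    ``unknown_residue='neutral'`` scores illegal residues as 0 everywhere
    instead of raising.
    """
    if not seq:
        raise ValueError("empty sequence")
    idx = _encode(seq, unknown_residue)
    S = profile.scores
    m, n = S.shape[0], idx.size

    # match-score matrix row per profile column; unknown residues score 0
    NEG = -1e18
    # M[i, j]: col i aligned to residue j; X: profile column gapped against
    # sequence (deletion); Y: sequence residue inserted.
    M_prev = np.full(n + 1, NEG)
    X_prev = np.full(n + 1, NEG)
    Y_prev = np.full(n + 1, NEG)
    M_prev[0] = 0.0
    js = np.arange(1, n + 1, dtype=float)
    Y_prev[1:] = -gap_open - (js - 1) * gap_extend

    ext = gap_extend * np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        row_scores = np.where(idx >= 0, S[i - 1, np.maximum(idx, 0)], 0.0)
        M_cur = np.full(n + 1, NEG)
        X_cur = np.maximum(M_prev - gap_open, X_prev - gap_extend)
        best_prev = np.maximum(np.maximum(M_prev, X_prev), Y_prev)
        M_cur[1:] = best_prev[:-1] + row_scores
        # Y recurrence unrolled: Y[i,j] = max_{k<j}(M/X[i,k]) - open - ext*(j-1-k)
        base = np.maximum(M_cur, X_cur) + ext
        run = np.maximum.accumulate(base[:-1])
        Y_cur = np.full(n + 1, NEG)
        Y_cur[1:] = run - gap_open - ext[1:] + gap_extend
        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur

    return float(max(M_prev[n], X_prev[n], Y_prev[n]))


@dataclass
class HitRecord:
    profile: str
    genome_id: str
    sequence_id: str
    bitscore: float
    delta_bitscore: float
    passed_filter: bool


def delta_bitscore(profile: ProfileModel, reference_seq: str,
                   queries: list[tuple[str, str]], **score_kwargs
                   ) -> list[HitRecord]:
    """Delta bitscore (reference bitscore minus query bitscore) of each
    query against the profile; a query identical to the reference has
    delta 0 by construction."""
    ref_score = score_sequence(profile, reference_seq, **score_kwargs)
    hits = []
    for name, seq in queries:
        s = score_sequence(profile, seq, **score_kwargs)
        hits.append(HitRecord(profile=profile.name, genome_id="",
                              sequence_id=name, bitscore=s,
                              delta_bitscore=ref_score - s,
                              passed_filter=True))
    return hits


def screen_gene_sets(profiles: dict[str, ProfileModel],
                     gene_sets: dict[str, list[tuple[str, str]]],
                     score_min: float,
                     reference_genome: str | None = None,
                     **score_kwargs) -> list[HitRecord]:
    """Screen per-genome gene sets against every profile.

    The best-scoring sequence per (profile, genome) is retained;
    ``passed_filter`` iff its bitscore >= ``score_min``.  If
    ``reference_genome`` is given, deltas are computed against its best
    hit per profile (zero for the reference itself); otherwise deltas are
    NaN.  An empty gene set yields a no-hit record (NaN bitscore).
    """
    if not profiles or not gene_sets:
        raise ValueError("need at least one profile and one gene set")
    if reference_genome is not None and reference_genome not in gene_sets:
        raise ValueError(f"reference genome {reference_genome!r} not in gene sets")

    best: dict[tuple[str, str], HitRecord] = {}
    for pname, prof in sorted(profiles.items()):
        for genome, genes in sorted(gene_sets.items()):
            top_id, top_score = None, -np.inf
            for sid, seq in genes:
                s = score_sequence(prof, seq, **score_kwargs)
                if s > top_score:
                    top_id, top_score = sid, s
            if top_id is None:
                best[(pname, genome)] = HitRecord(
                    profile=pname, genome_id=genome, sequence_id="",
                    bitscore=float("nan"), delta_bitscore=float("nan"),
                    passed_filter=False)
            else:
                best[(pname, genome)] = HitRecord(
                    profile=pname, genome_id=genome, sequence_id=top_id,
                    bitscore=top_score, delta_bitscore=float("nan"),
                    passed_filter=bool(top_score >= score_min))

    for pname in profiles:
        ref = (best[(pname, reference_genome)].bitscore
               if reference_genome is not None else float("nan"))
        for genome in gene_sets:
            hit = best[(pname, genome)]
            if not math.isnan(hit.bitscore):
                hit.delta_bitscore = ref - hit.bitscore

    return [best[k] for k in sorted(best)]


def conservation_heatmap(hits: list[HitRecord]) -> pd.DataFrame:
    """Genes (profiles) x genomes matrix of delta bitscores; NaN where no
    hit passed the filter.  The reference genome's column is all-zero for
    its own genes by the delta-bitscore definition."""
    profiles = sorted({h.profile for h in hits})
    genomes = sorted({h.genome_id for h in hits})
    mat = pd.DataFrame(np.nan, index=profiles, columns=genomes)
    for h in hits:
        if h.passed_filter and not math.isnan(h.delta_bitscore):
            mat.loc[h.profile, h.genome_id] = h.delta_bitscore
    mat.index.name = "profile"
    return mat


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def find_palindromic_operators(upstream_seq: str, motif_len: int = 16,
                               window: tuple[int, int] = (20, 40),
                               max_mismatches: int = 0
                               ) -> list[tuple[int, str]]:
    """Scan for reverse-complement palindromes upstream of a reference point.

    Offsets are 1-based distances measured upstream from the 3' end of
    ``upstream_seq`` to the motif's downstream edge: at offset o the motif
    occupies ``seq[L-o-motif_len : L-o]``.  A k-mer is palindromic when it
    equals its own reverse complement; ``max_mismatches`` symmetric base
    pairs may violate complementarity.  Returns (offset, motif) hits for
    every offset in ``window`` (inclusive).
    """
    seq = upstream_seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A, C, G, T}")
    lo, hi = window
    if lo < 0 or hi < lo:
        raise ValueError("window must satisfy 0 <= start <= end")
    if motif_len < 2:
        raise ValueError("motif_len must be >= 2")
    L = len(seq)
    if L < hi + motif_len:
        raise ValueError("sequence shorter than window end + motif length")

    hits = []
    for offset in range(lo, hi + 1):
        motif = seq[L - offset - motif_len: L - offset]
        mism = sum(
            1 for i in range((motif_len + 1) // 2)
            if motif[i] != _COMPLEMENT[motif[motif_len - 1 - i]]
        )
        if mism <= max_mismatches:
            hits.append((offset, motif))
    return hits
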