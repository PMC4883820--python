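"""Kinase-domain detection with a position-specific scoring profile.

The screening stage condenses a seed alignment of the eukaryotic
protein-kinase catalytic domain into a per-column log-odds profile and
locates scored occurrences of the whole domain inside each protein by
dynamic programming.  Alignment is *glocal*: the full profile must be
consumed, while any substring of the protein may carry it, with affine gap
penalties on both sides.

Scores are converted to E-values through an empirical Gumbel calibration:
the maximal profile score is computed for a fixed number of random
background sequences (fixed internal seed), a Gumbel distribution is fitted
to those maxima, and the fitted location/scale yield the ``(lambda, K)``
pair of the classic extreme-value formula

    E = K * search_space * profile_length * 2**(-bit_score)

where ``bit_score = lambda * raw_score / ln 2`` is the calibrated score in
bits.  Proteins are screened at a non-stringent default cutoff of 1e-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ALPHABET, AMINO_ACIDS, ProteinRecord, read_alignment

_NEG = -1.0e30
_ENCODE = {a: i for i, a in enumerate(ALPHABET)}
_X = _ENCODE["X"]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein string onto integer codes over the 21-letter alphabet."""
    return np.fromiter((_ENCODE.get(a, _X) for a in seq), dtype=np.intp,
                       count=len(seq))


@dataclass
class DomainProfile:
    """Position-specific log-odds profile of the kinase catalytic domain.

    ``match_scores`` holds one row per match state with log2-odds scores for
    the 20 canonical residues; the trailing X column is neutral (0 bits).
    ``calibration`` is the fitted ``(lambda, K)`` pair; ``lambda`` rescales
    raw profile scores to bits and ``K`` sets the search-space prefactor.
    """

    match_scores: np.ndarray           # (length, 21), bits
    background: np.ndarray             # (20,), sums to 1
    gap_open: float
    gap_extend: float
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError(f"profile too short ({self.length} match states)")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.calibration is not None:
            lam, k = self.calibration
            if lam <= 0 or k <= 0:
                raise ValueError("calibration requires lambda > 0 and K > 0")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-scoring residue of each match state."""
        idx = np.argmax(self.match_scores[:, :20], axis=1)
        return "".join(AMINO_ACIDS[i] for i in idx)

    def bit_score(self, raw_score: float) -> float:
        if self.calibration is None:
            raise ValueError("profile is not calibrated")
        lam, _ = self.calibration
        return lam * raw_score / math.log(2.0)


@dataclass(frozen=True)
class DomainHit:
    """A located kinase-domain match (0-based half-open coordinates)."""

    protein_id: str
    start: int
    end: int
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("hit interval must satisfy 0 <= start < end")
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profile(
    seed: str | Path | tuple[Sequence[str], Sequence[str]],
    pseudocount_weight: float = 1.0,
    *,
    gap_open: float = 5.0,
    gap_extend: float = 0.5,
    min_occupancy: float = 0.5,
    calibrate: bool = True,
    n_calibration: int = 1000,
    calibration_length: int = 400,
    calibration_seed: int = 20831,
) -> DomainProfile:
    """Build a log-odds profile from a seed alignment.

    ``seed`` is an aligned-FASTA path or a pre-parsed ``(ids, rows)`` pair.
    Columns with fewer than ``min_occupancy`` non-gap residues are dropped
    from the match states.  Per retained column *i* and residue *a*,

        score[i][a] = log2( (c_ia + w * bg_a) / (n_i + w) / bg_a )

    with ``c_ia`` the residue count, ``n_i`` the column occupancy, ``w`` the
    pseudocount weight and ``bg`` the smoothed background frequencies of the
    seed.  When ``calibrate`` is set, ``n_calibration`` background sequences
    of ``calibration_length`` residues are scored with a fixed seed and a
    Gumbel fit of their maxima provides ``(lambda, K)``.
    """
    if isinstance(seed, (str, Path)):
        ids, rows = read_alignment(seed)
    else:
        ids, rows = seed
    if len(rows) < 2:
        raise ValueError("profile construction requires >= 2 aligned sequences")

    aln = np.array([list(r) for r in rows])
    n_cols = aln.shape[1]

    # background from all non-gap, non-X residues, Laplace-smoothed
    residues = aln[(aln != "-") & (aln != "X")]
    bg_counts = np.zeros(20)
    for i, a in enumerate(AMINO_ACIDS):
        bg_counts[i] = np.count_nonzero(residues == a)
    background = (bg_counts + 1.0) / (bg_counts.sum() + 20.0)
    background /= background.sum()

    occupancy = (aln != "-").mean(axis=0)
    keep = occupancy >= min_occupancy
    if not keep.any():
        raise ValueError("all columns fall below the occupancy threshold")

    w = float(pseudocount_weight)
    scores = np.zeros((int(keep.sum()), 21))
    out_i = 0
    for col in range(n_cols):
        if not keep[col]:
            continue
        column = aln[:, col]
        counts = np.zeros(20)
        for i, a in enumerate(AMINO_ACIDS):
            counts[i] = np.count_nonzero(column == a)
        n_i = counts.sum()
        probs = (counts + w * background) / (n_i + w)
        scores[out_i, :20] = np.log2(probs / background)
        scores[out_i, 20] = 0.0  # X is neutral
        out_i += 1

    profile = DomainProfile(
        match_scores=scores,
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )
    if calibrate:
        profile.calibration = _calibrate(
            profile, n_calibration, calibration_length, calibration_seed
        )
    return profile


def _calibrate(profile: DomainProfile, n: int, length: int,
               seed: int) -> tuple[float, float]:
    """Fit a Gumbel law to maximal scores of random background sequences."""
    rng = np.random.default_rng(seed)
    maxima = np.empty(n)
    for i in range(n):
        enc = rng.choice(20, size=length, p=profile.background)
        maxima[i] = _glocal_dp(
            profile.match_scores[:, enc],
            profile.gap_open, profile.gap_extend,
        )[0]
    loc, scale = stats.gumbel_r.fit(maxima)
    lam = 1.0 / scale
    k = math.exp(loc / scale) / (length * profile.length)
    return lam, k


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def evalue(bit_score: float, profile: DomainProfile,
           search_space: int) -> float:
    """Expected chance hits at or above ``bit_score`` in ``search_space`` residues."""
    if search_space <= 0:
        raise ValueError("search_space must be positive")
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    _, k = profile.calibration
    return k * search_space * profile.length * math.exp2(-bit_score)


# ---------------------------------------------------------------------------
# glocal dynamic programming
# ---------------------------------------------------------------------------

def _glocal_dp(smat: np.ndarray, gap_open: float, gap_extend: float,
               keep: bool = False):
    """Best glocal alignment score of a profile-vs-sequence score matrix.

    ``smat`` has shape (L, n): per-position profile scores of the sequence
    residues.  Returns ``(score, matrices_or_None, end_jj)`` where ``jj`` is
    the number of consumed sequence characters at the optimal end.  States:
    M (residue consumed by a match state), D (match state skipped), I
    (residue inserted between match states).  Sequence prefix and suffix are
    free; the whole profile must be consumed.
    """
    L, n = smat.shape
    jj_ext = gap_extend * np.arange(n + 1)

    M_rows = np.empty((L, n + 1)) if keep else None
    D_rows = np.empty((L, n + 1)) if keep else None
    I_rows = np.empty((L, n + 1)) if keep else None

    M_prev = D_prev = I_prev = None
    for i in range(L):
        M = np.full(n + 1, _NEG)
        if i == 0:
            M[1:] = smat[0]
            D = np.full(n + 1, -gap_open)
        else:
            best_prev = np.maximum(np.maximum(M_prev, D_prev), I_prev)
            M[1:] = smat[i] + best_prev[:-1]
            D = np.maximum(M_prev - gap_open, D_prev - gap_extend)
        # I[jj] = max(M[jj-1] - open, I[jj-1] - extend) via prefix maximum
        V = np.full(n + 1, _NEG)
        V[1:] = M[:-1] - gap_open + jj_ext[1:]
        I = np.maximum.accumulate(V) - jj_ext
        if keep:
            M_rows[i], D_rows[i], I_rows[i] = M, D, I
        M_prev, D_prev, I_prev = M, D, I

    finals = np.maximum(M_prev, D_prev)
    end_jj = int(np.argmax(finals))
    score = float(finals[end_jj])
    if keep:
        return score, (M_rows, D_rows, I_rows), end_jj
    return score, None, end_jj


def _traceback(smat: np.ndarray, mats, end_jj: int,
               gap_open: float, gap_extend: float) -> list[tuple[str, int, int]]:
    """Recover one optimal path as ``(state, profile_row, seq_index)`` triples.

    ``seq_index`` is -1 for deletion states.  Ties are resolved in the fixed
    order M, D, I so identical inputs always yield identical paths.
    """
    M, D, I = mats
    L = smat.shape[0]
    i, jj = L - 1, end_jj
    state = "M" if M[i, jj] >= D[i, jj] else "D"
    path: list[tuple[str, int, int]] = []
    tol = 1e-6
    while True:
        if state == "M":
            path.append(("M", i, jj - 1))
            if i == 0:
                break
            target = M[i, jj] - smat[i, jj - 1]
            if abs(M[i - 1, jj - 1] - target) <= tol:
                state = "M"
            elif abs(D[i - 1, jj - 1] - target) <= tol:
                state = "D"
            else:
                state = "I"
            i, jj = i - 1, jj - 1
        elif state == "D":
            path.append(("D", i, -1))
            if i == 0:
                break
            if abs(M[i - 1, jj] - gap_open - D[i, jj]) <= tol:
                state = "M"
            else:
                state = "D"
            i -= 1
        else:  # I
            path.append(("I", i, jj - 1))
            if abs(M[i, jj - 1] - gap_open - I[i, jj]) <= tol:
                state = "M"
            else:
                state = "I"
            jj -= 1
    path.reverse()
    return path


def align_sequence_to_profile(sequence: str, profile: DomainProfile):
    """Glocal-align one sequence; returns ``(raw_score, path)``."""
    enc = encode_sequence(sequence)
    smat = profile.match_scores[:, enc]
    score, mats, end_jj = _glocal_dp(smat, profile.gap_open,
                                     profile.gap_extend, keep=True)
    path = _traceback(smat, mats, end_jj, profile.gap_open, profile.gap_extend)
    return score, path


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_protein(protein: ProteinRecord, profile: DomainProfile,
                 e_cutoff: float = 1e-2, max_hits: int = 16) -> list[DomainHit]:
    """Locate all non-overlapping domain hits with ``E <= e_cutoff``.

    Hits are found greedily by descending score: the best-scoring occurrence
    is reported, its residues are masked, and the scan repeats until no
    remaining occurrence passes the cutoff.  Hits are returned sorted by
    start coordinate.  Proteins shorter than 10 residues yield no hits.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    n = len(protein.sequence)
    if n < 10:
        return []
    enc = encode_sequence(protein.sequence)
    smat = profile.match_scores[:, enc].copy()
    hits: list[DomainHit] = []
    for _ in range(max_hits):
        score, mats, end_jj = _glocal_dp(smat, profile.gap_open,
                                         profile.gap_extend, keep=True)
        bit = profile.bit_score(score)
        e = evalue(bit, profile, n)
        if e > e_cutoff:
            break
        path = _traceback(smat, mats, end_jj, profile.gap_open,
                          profile.gap_extend)
        consumed = [j for _, _, j in path if j >= 0]
        if not consumed:
            break
        start, end = min(consumed), max(consumed) + 1
        if any(h.start < end and start < h.end for h in hits):
            break  # bridged a masked region; nothing new to report
        hits.append(DomainHit(protein.id, start, end, bit, e))
        smat[:, start:end] = _NEG
    return sorted(hits, key=lambda h: h.start)


def scan_proteome(proteins: Sequence[ProteinRecord], profile: DomainProfile,
                  e_cutoff: float = 1e-2) -> dict[str, list[DomainHit]]:
    """Scan every protein; returns only proteins with at least one hit."""
    out: dict[str, list[DomainHit]] = {}
    for prot in proteins:
        hits = scan_protein(prot, profile, e_cutoff)
        if hits:
            out[prot.id] = hits
    return out
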