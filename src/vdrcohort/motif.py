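"""PWM scanning, exact score p-values, ZOOPS EM discovery and iterative
motif refinement.

The refinement loop mirrors the scan-then-rediscover strategy used to
derive cell-type-specific variants of a receptor recognition motif: the
sequence set is scanned with the current matrix at a per-window p-value
threshold, the positive sequences are handed to EM-based de novo
discovery, and the rediscovered matrix seeds the next round.  Left
unchecked this loop degenerates into low-information motifs, so rounds
stop when the mean per-column information content falls below a floor.

Score p-values are exact under the background model: per-position
log-odds scores are discretized to a common step and convolved by dynamic
programming, giving the full null score distribution (the FIMO approach).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .util import round_half_up as _round_half_up

__all__ = [
    "PWM",
    "ScoreDistribution",
    "MotifHit",
    "pwm_from_counts",
    "score_pvalue_table",
    "scan_sequences",
    "partition_by_motif",
    "em_motif_discovery",
    "iterative_refinement",
    "motif_count_curve",
    "read_fasta",
    "write_fasta",
    "read_jaspar",
    "write_jaspar",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])
UNIFORM = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N etc.) -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class PWM:
    """Position weight matrix: per-column base probabilities plus the
    background model they are scored against."""

    probs: np.ndarray                      # (4, width), columns sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x width matrix")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), with zero probabilities floored."""
        p = np.maximum(self.probs, 1e-10)
        return np.log2(p / self.background[:, None])

    @property
    def information_content(self) -> np.ndarray:
        """Per-column IC in bits against a uniform background."""
        p = np.maximum(self.probs, 1e-12)
        return 2.0 + (p * np.log2(p)).sum(axis=0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background.copy(),
                   self.pseudocount, self.name + "_rc")

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=self.probs[:, j]) for j in range(self.width)]
        return "".join(BASES[i] for i in cols)


def pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PWM:
    """Counts -> probabilities via (count + c) / (total + 4c)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x width matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("all-zero column needs a pseudocount")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    bg = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
    return PWM(probs, bg, pseudocount, name)


# ---------------------------------------------------------------------------
# exact score distribution
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    ``exceedance[k - offset]`` = P(score_int >= k) under the background.
    Scanning uses the same integer discretization, so hit p-values are
    exact up to one discretization step.
    """

    step: float
    offset: int                 # smallest attainable integer score
    exceedance: np.ndarray      # length span+1, monotone non-increasing
    int_scores: np.ndarray      # (4, width) discretized log-odds

    def pvalue_int(self, k: np.ndarray | int) -> np.ndarray | float:
        idx = np.clip(np.asarray(k) - self.offset, 0, len(self.exceedance) - 1)
        out = self.exceedance[idx]
        return float(out) if np.isscalar(k) else out

    def score_for_pvalue(self, p_max: float) -> int:
        """Smallest integer score whose exceedance is <= p_max."""
        ok = np.flatnonzero(self.exceedance <= p_max)
        if len(ok) == 0:
            return self.offset + len(self.exceedance)  # unattainable
        return self.offset + int(ok[0])


def score_pvalue_table(pwm: PWM, step: float | None = None, max_entries: int = 100_000) -> ScoreDistribution:
    """Dynamic-programming convolution of per-position score distributions
    under the background model.

    The step is chosen so the DP table has at most ``max_entries`` states
    (p-value error bounded by one step).
    """
    lo = pwm.log_odds
    if step is None:
        span = float((lo.max(axis=0) - lo.min(axis=0)).sum())
        step = max(span / max_entries, 1e-9)
    if step <= 0:
        raise ValueError("step must be positive")
    ints = np.round(lo / step).astype(np.int64)
    min_sum = int(ints.min(axis=0).sum())
    max_sum = int(ints.max(axis=0).sum())
    span = max_sum - min_sum
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    reach = 0  # current filled extent relative to running minimum
    run_min = 0
    bg = pwm.background
    for j in range(pwm.width):
        col = ints[:, j]
        cmin = int(col.min())
        new = np.zeros(span + 1)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift:shift + reach + 1] += bg[b] * dist[:reach + 1]
        reach += int(col.max()) - cmin
        run_min += cmin
        dist = new
    assert run_min == min_sum
    exceed = np.cumsum(dist[::-1])[::-1]
    exceed = np.minimum(exceed, 1.0)
    return ScoreDistribution(step=step, offset=min_sum, exceedance=exceed, int_scores=ints)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int          # 0-based window start on the forward strand
    strand: str          # '+' or '-'
    score: float         # log-odds (discretized)
    p_value: float
    best_in_sequence: bool = False


def _window_scores(codes: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score per window plus a validity mask (windows with N are invalid)."""
    w = ints.shape[1]
    if len(codes) < w:
        return np.empty(0, np.int64), np.empty(0, bool)
    win = sliding_window_view(codes, w)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = ints[safe, np.arange(w)].sum(axis=1)
    return scores, valid


def _as_seq_items(seqs) -> list[tuple[str, str]]:
    if isinstance(seqs, dict):
        return list(seqs.items())
    out = []
    for i, item in enumerate(seqs):
        if isinstance(item, tuple):
            out.append(item)
        else:
            out.append((f"seq{i+1}", str(item)))
    return out


def scan_sequences(
    seqs,
    pwm: PWM,
    p_max: float = 1e-4,
    both_strands: bool = True,
    table: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """All motif occurrences with exact p <= p_max.

    ``seqs`` may be a dict {id: sequence}, a list of (id, sequence) pairs
    or a plain list of sequences.  Windows containing N are skipped.  The
    best (lowest-p) hit of each sequence is flagged.
    """
    table = table or score_pvalue_table(pwm)
    ints = table.int_scores
    rc_ints = ints[::-1, ::-1]
    threshold = table.score_for_pvalue(p_max)
    hits: list[MotifHit] = []
    for seq_id, seq in _as_seq_items(seqs):
        codes = encode(str(seq))
        seq_hits = []
        strands = [("+", ints)] + ([("-", rc_ints)] if both_strands else [])
        for strand, mat in strands:
            scores, valid = _window_scores(codes, mat)
            sel = np.flatnonzero(valid & (scores >= threshold))
            for o in sel:
                k = int(scores[o])
                seq_hits.append(MotifHit(seq_id, int(o), strand,
                                         k * table.step, float(table.pvalue_int(k))))
        if seq_hits:
            best = min(range(len(seq_hits)), key=lambda i: (seq_hits[i].p_value, seq_hits[i].offset))
            seq_hits = [MotifHit(h.seq_id, h.offset, h.strand, h.score, h.p_value, i == best)
                        for i, h in enumerate(seq_hits)]
        hits.extend(seq_hits)
    return hits


def partition_by_motif(
    seqs,
    pwm: PWM,
    p_max: float = 1e-4,
    both_strands: bool = True,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], float]:
    """Split sequences into those with >=1 hit at p <= p_max and the rest.

    Returns (positives, negatives, positive percentage to 1 decimal).
    """
    items = _as_seq_items(seqs)
    hit_ids = {h.seq_id for h in scan_sequences(items, pwm, p_max, both_strands)}
    pos = [it for it in items if it[0] in hit_ids]
    neg = [it for it in items if it[0] not in hit_ids]
    frac = _round_half_up(100.0 * len(pos) / len(items), 1) if items else 0.0
    return pos, neg, frac


# ---------------------------------------------------------------------------
# ZOOPS EM discovery
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    pwm: PWM
    gamma: float                    # estimated fraction of sequences with a site
    log_likelihood: float
    site_posteriors: list[np.ndarray]   # per sequence: P(site at each offset)
    ll_trace: list[float] = field(default_factory=list)

    @property
    def mean_ic(self) -> float:
        return float(self.pwm.information_content.mean())


def _background_from_seqs(items: list[tuple[str, str]]) -> np.ndarray:
    counts = np.ones(4)  # +1 smoothing
    for _, seq in items:
        codes = encode(str(seq))
        counts += np.bincount(codes[codes >= 0], minlength=4)
    return counts / counts.sum()


def em_motif_discovery(
    seqs,
    width: int,
    n_starts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> EMResult:
    """Single-motif ZOOPS (zero-or-one occurrence per sequence) EM.

    Each sequence either contains one site at a uniformly-chosen offset
    (prior gamma) or is pure background.  The best of ``n_starts`` random
    restarts by final log-likelihood is returned; the log-likelihood is
    non-decreasing within every run.
    """
    items = _as_seq_items(seqs)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    if any(len(s) < width for _, s in items):
        raise ValueError("width exceeds the shortest sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = _background_from_seqs(items) if background is None else np.asarray(background, float)

    coded = [encode(str(s)) for _, s in items]
    windows = []
    for codes in coded:
        win = sliding_window_view(codes, width)
        valid = (win >= 0).all(axis=1)
        windows.append((np.where(win >= 0, win, 0), valid))

    def run(theta: np.ndarray, gamma: float):
        trace = []
        ll_prev = -np.inf
        posts = None
        for _ in range(max_iter):
            ratio = np.maximum(theta, 1e-10) / bg[:, None]
            ll = 0.0
            posts = []
            counts = np.full((4, width), pseudocount)
            gamma_num = 0.0
            for win, valid in windows:
                m = len(win)
                r = ratio[win, np.arange(width)].prod(axis=1)
                r = np.where(valid, r, 0.0)
                mix = (1.0 - gamma) + gamma / m * r.sum()
                ll += np.log(max(mix, 1e-300))
                z = (gamma / m * r) / max(mix, 1e-300)
                posts.append(z)
                gamma_num += z.sum()
                # expected base counts at each motif position
                keep = z > 1e-12
                if keep.any():
                    zk = z[keep]
                    wk = win[keep]
                    for j in range(width):
                        np.add.at(counts[:, j], wk[:, j], zk)
            theta = counts / counts.sum(axis=0)
            gamma = min(max(gamma_num / len(windows), 1e-4), 1 - 1e-4)
            trace.append(ll)
            if ll - ll_prev < tol and len(trace) > 1:
                break
            ll_prev = ll
        return theta, gamma, trace[-1], posts, trace

    best = None
    for _ in range(n_starts):
        # seed the motif from a random subsequence, smoothed
        _, seq = items[rng.integers(len(items))]
        codes = encode(str(seq))
        starts_ok = np.flatnonzero(
            (sliding_window_view(codes, width) >= 0).all(axis=1))
        if len(starts_ok) == 0:
            init = rng.dirichlet(np.ones(4), size=width).T
        else:
            o = int(rng.choice(starts_ok))
            init = np.full((4, width), 0.1)
            init[codes[o:o + width], np.arange(width)] = 0.7
        init /= init.sum(axis=0)
        theta, gamma, ll, posts, trace = run(init, 0.5)
        if best is None or ll > best[2]:
            best = (theta, gamma, ll, posts, trace)

    theta, gamma, ll, posts, trace = best
    pwm = PWM(theta, bg, pseudocount, name="em_motif")
    return EMResult(pwm, float(gamma), float(ll), posts, trace)


# ---------------------------------------------------------------------------
# iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementRound:
    round: int
    n_positive: int
    mean_ic: float


@dataclass
class RefinementResult:
    pwm: PWM
    history: list[RefinementRound]
    degenerate: bool = False


def iterative_refinement(
    seqs,
    seed_pwm: PWM,
    p_scan: float = 1e-4,
    rounds: int = 2,
    min_ic_per_col: float = 0.3,
    min_positives: int = 10,
    em_starts: int = 3,
    seed: int | np.random.Generator | None = None,
) -> RefinementResult:
    """Alternate PWM scanning and EM rediscovery to adapt a seed motif to a
    sequence set.

    Each round scans with the current matrix at ``p_scan``, runs ZOOPS EM
    on the positive sequences at the seed's width, and adopts the
    rediscovered matrix.  Stops after ``rounds`` rounds, when the positive
    set falls below ``min_positives`` (re-estimating from a handful of
    chance hits only overfits them), or when mean per-column IC drops
    below ``min_ic_per_col`` (the result is then flagged degenerate and
    the last non-degenerate matrix is returned).
    """
    items = _as_seq_items(seqs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = seed_pwm
    history: list[RefinementRound] = []
    for r in range(1, rounds + 1):
        pos, _, _ = partition_by_motif(items, current, p_scan)
        if len(pos) < max(min_positives, 2):
            history.append(RefinementRound(r, len(pos), float(current.information_content.mean())))
            return RefinementResult(current, history, degenerate=False)
        em = em_motif_discovery(pos, seed_pwm.width, n_starts=em_starts, seed=rng)
        mean_ic = em.mean_ic
        history.append(RefinementRound(r, len(pos), mean_ic))
        if mean_ic < min_ic_per_col:
            return RefinementResult(current, history, degenerate=True)
        current = em.pwm
    return RefinementResult(current, history, degenerate=False)


def motif_count_curve(seqs, pwm: PWM, p_grid: Sequence[float], both_strands: bool = True):
    """Number of sequences with >=1 hit, as a function of the p threshold.

    The size-corrected p multiplies each threshold by the number of scanned
    windows (tests), capped at 1.  Returns a pandas DataFrame
    (p, count, corrected_p).
    """
    import pandas as pd

    p_grid = list(p_grid)
    if p_grid != sorted(p_grid):
        raise ValueError("p_grid must be sorted ascending")
    items = _as_seq_items(seqs)
    table = score_pvalue_table(pwm)
    n_tests = 0
    best_p: list[float] = []
    ints, rc = table.int_scores, table.int_scores[::-1, ::-1]
    for _, seq in items:
        codes = encode(str(seq))
        seq_best = np.inf
        for mat in ([ints, rc] if both_strands else [ints]):
            scores, valid = _window_scores(codes, mat)
            n_tests += int(valid.sum())
            if valid.any():
                seq_best = min(seq_best, float(table.pvalue_int(int(scores[valid].max()))))
        best_p.append(seq_best)
    best_p = np.array(best_p)
    rows = [(p, int((best_p <= p).sum()), min(1.0, p * n_tests)) for p in p_grid]
    return pd.DataFrame(rows, columns=["p", "count", "corrected_p"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with open(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(items: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_jaspar(path: str | Path) -> np.ndarray:
    """JASPAR-style count matrix: four lines 'A [ 1 2 ... ]' etc."""
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            base = line[0].upper()
            if base in _CODE:
                nums = line[1:].strip().lstrip("[").rstrip("]").split()
                rows[base] = [float(x) for x in nums if x not in "[]"]
    if set(rows) != set(BASES):
        raise ValueError(f"{path}: expected A/C/G/T count rows")
    return np.array([rows[b] for b in BASES])


def write_jaspar(counts: np.ndarray, path: str | Path, name: str = "motif") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, b in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in counts[i])
            fh.write(f"{b} [ {vals} ]\n")
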