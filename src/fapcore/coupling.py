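"""Coevolution-based contact prediction from multiple sequence alignments.

Residue pairs that covary across a deep alignment of homologs tend to be in
physical contact.  Two estimators are provided:

* a mutual-information baseline with average-product correction (MI-APC), and
* a regularized pseudolikelihood Potts model (plmDCA-style): a 21-state
  (20 amino acids + gap) pairwise maximum-entropy model whose coupling blocks,
  summarised by their Frobenius norm after gauge fixing and APC, rank
  candidate contacts.

Scores are reported on a scaled, unitless axis built in two steps: the
APC-corrected coupling norms are soft-thresholded at twice their robust
(median-absolute-deviation) spread — pure estimation noise collapses to
zero — and the surviving scores are normalized so their positive mean is 1.
On that scale "> 2.0" reads as "twice the average significant coupling
signal", and on alignments with no covariance structure essentially no pair
scores above 2.  This is a convention of this package chosen to be
comparable to published GREMLIN-style score thresholds, not a reproduction
of any particular program's internal scale.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.optimize import minimize

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = 20
Q = 21

_CHAR_TO_STATE = {c: i for i, c in enumerate(ALPHABET)}


# ---------------------------------------------------------------------------
# MSA input and encoding
# ---------------------------------------------------------------------------

def read_msa(stream: TextIO | str) -> list[str]:
    """Read an aligned FASTA (A2M tolerated: lowercase columns -> gap)."""
    from Bio import SeqIO

    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    records = list(SeqIO.parse(stream, "fasta"))
    seqs = []
    for rec in records:
        s = str(rec.seq)
        # A2M: lowercase = insertion relative to the match states -> mask to gap
        s = "".join("-" if c.islower() or c == "." else c for c in s)
        seqs.append(s)
    if seqs and len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned FASTA requires equal-length sequences")
    return seqs


def encode_msa(seqs: Sequence[str] | np.ndarray) -> np.ndarray:
    """Encode sequences as an N x L int8 matrix over 21 states (gap = 20).

    Unknown characters (X, B, Z, ...) are mapped to the gap state.
    """
    if isinstance(seqs, np.ndarray) and seqs.dtype.kind in "iu":
        return seqs.astype(np.int8)
    if len(seqs) == 0:
        raise ValueError("empty MSA")
    out = np.empty((len(seqs), len(seqs[0])), dtype=np.int8)
    for n, s in enumerate(seqs):
        if len(s) != out.shape[1]:
            raise ValueError("all sequences must have the same length")
        out[n] = [_CHAR_TO_STATE.get(c, GAP) for c in s.upper()]
    return out


@dataclass
class WeightedMSA:
    """Encoded alignment with sequence weights and column bookkeeping.

    ``weights[n] = 1 / |{m : identity(n, m) >= id_threshold}|`` (the sequence
    itself included), the standard redundancy correction of DCA;
    ``effective_n`` is their sum.  ``masked`` flags columns excluded from
    fitting (gap fraction > ``max_gap_frac`` or unmappable to the reference);
    ``ref_positions`` maps alignment columns to 1-based positions in the
    ungapped first (reference) sequence, -1 where the reference has a gap.
    """

    matrix: np.ndarray
    weights: np.ndarray
    effective_n: float
    id_threshold: float
    masked: np.ndarray = field(default=None)
    ref_positions: np.ndarray = field(default=None)

    def __post_init__(self):
        N, L = self.matrix.shape
        if self.ref_positions is None:
            ref = self.matrix[0]
            pos, refpos = 0, np.full(L, -1, dtype=int)
            for j in range(L):
                if ref[j] != GAP:
                    pos += 1
                    refpos[j] = pos
            self.ref_positions = refpos
        if self.masked is None:
            self.masked = np.zeros(L, dtype=bool)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def msa_weights(
    msa: Sequence[str] | np.ndarray,
    id_threshold: float = 0.8,
    max_gap_frac: float = 0.5,
    chunk: int = 256,
) -> WeightedMSA:
    """Compute redundancy weights and column masks for an alignment.

    Identity between two sequences is the fraction of identical residues over
    columns where neither is a gap (0 if no such columns).  Columns with more
    than ``max_gap_frac`` gaps, or where the reference (first) sequence is
    gapped, are masked from fitting and reported via ``WeightedMSA.masked``.
    """
    X = encode_msa(msa)
    N, L = X.shape
    if N == 0 or L == 0:
        raise ValueError("empty MSA")
    nongap = (X != GAP).astype(np.float32)
    # one-hot BLAS trick: pairwise match counts over non-gap-pair columns
    oh = np.zeros((N, L * Q), dtype=np.float32)
    oh[np.repeat(np.arange(N), L),
       ((np.arange(L) * Q)[None, :] + X.astype(np.int64)).ravel()] = 1.0
    oh *= np.repeat(nongap, Q, axis=1)
    counts = np.zeros(N, dtype=np.int64)
    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        matches = oh[lo:hi] @ oh.T          # matches over both-non-gap columns
        denom = nongap[lo:hi] @ nongap.T
        ident = np.divide(matches, denom, out=np.zeros_like(matches),
                          where=denom > 0)
        counts[lo:hi] = (ident >= id_threshold - 1e-9).sum(axis=1)
    weights = 1.0 / counts
    wmsa = WeightedMSA(
        matrix=X, weights=weights, effective_n=float(weights.sum()),
        id_threshold=id_threshold,
    )
    gap_frac = (X == GAP).mean(axis=0)
    wmsa.masked = (gap_frac > max_gap_frac) | (wmsa.ref_positions < 0)
    return wmsa


# ---------------------------------------------------------------------------
# MI-APC baseline
# ---------------------------------------------------------------------------

def apc_correct(scores: np.ndarray) -> np.ndarray:
    """Average product correction: S_ij - mean_i * mean_j / mean, diag zero."""
    S = np.array(scores, dtype=float)
    np.fill_diagonal(S, 0.0)
    L = S.shape[0]
    if L < 2:
        return S
    row_mean = S.sum(axis=1) / (L - 1)
    grand = S.sum() / (L * (L - 1))
    if grand == 0:
        return S
    corr = S - np.outer(row_mean, row_mean) / grand
    np.fill_diagonal(corr, 0.0)
    return corr


def mi_apc(wmsa: WeightedMSA, pseudocount: float = 1.0) -> np.ndarray:
    """APC-corrected weighted mutual information between all column pairs.

    Joint frequencies receive ``pseudocount`` observations per state pair
    (strong shrinkage that suppresses the finite-sample MI bias); marginals
    are derived from the smoothed joints, so MI is always non-negative.
    Masked columns get zero rows/columns.  Returns a symmetric L x L matrix
    with zero diagonal.
    """
    X, w = wmsa.matrix, wmsa.weights
    N, L = X.shape
    if L < 2:
        raise ValueError("MI requires at least two columns")
    neff = w.sum()

    mi = np.zeros((L, L))
    cols = [c for c in range(L) if not wmsa.masked[c]]
    for a_idx, i in enumerate(cols):
        xi = X[:, i].astype(np.int64)
        for j in cols[a_idx + 1:]:
            joint = np.bincount(xi * Q + X[:, j], weights=w, minlength=Q * Q)
            f2 = (joint.reshape(Q, Q) + pseudocount) / (neff + pseudocount * Q * Q)
            fi, fj = f2.sum(axis=1), f2.sum(axis=0)
            mi_ij = float((f2 * (np.log(f2) - np.log(np.outer(fi, fj)))).sum())
            mi[i, j] = mi[j, i] = mi_ij
    return apc_correct(mi)


# ---------------------------------------------------------------------------
# pseudolikelihood Potts fit
# ---------------------------------------------------------------------------

@dataclass
class PlmResult:
    """Fitted Potts parameters.  ``J`` is L x Q x L x Q, symmetric in
    (i, a) <-> (j, b) with zero self-blocks; ``h`` is L x Q."""

    J: np.ndarray
    h: np.ndarray
    converged: bool
    n_iter: int
    lambda_h: float
    lambda_J: float


def plm_fit(
    wmsa: WeightedMSA,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    max_iter: int = 100,
    gtol: float = 1e-3,
) -> PlmResult:
    """Fit a pairwise Potts model by L2-regularized pseudolikelihood.

    The symmetric parameterization is optimized jointly over all sites with
    L-BFGS from zero initialization (deterministic — no randomness involved).
    ``lambda_J`` defaults to ``0.1 * (L - 1)`` with L the number of fitted
    columns.  Masked columns are excluded from the fit; their coupling blocks
    are zero in the returned tensor (indexed over all alignment columns).

    Non-convergence within ``max_iter`` is reported through the ``converged``
    flag (with a warning), never silently.
    """
    # constant columns carry no coupling information (their apparent
    # couplings are gauge-spread field terms) and are excluded from the fit
    variable = np.array([np.unique(wmsa.matrix[:, j]).size > 1
                         for j in range(wmsa.length)])
    keep = np.flatnonzero(~wmsa.masked & variable)
    Lk = keep.size
    if lambda_J is None and Lk >= 2:
        lambda_J = 0.1 * (Lk - 1)
    if Lk < 2:
        # nothing to couple: the regularized optimum is exactly zero
        return PlmResult(
            J=np.zeros((wmsa.length, Q, wmsa.length, Q)),
            h=np.zeros((wmsa.length, Q)), converged=True, n_iter=0,
            lambda_h=lambda_h, lambda_J=lambda_J if lambda_J is not None else 0.0,
        )
    X = wmsa.matrix[:, keep].astype(np.int64)
    w = wmsa.weights
    N = X.shape[0]
    if wmsa.effective_n <= 1 + 1e-12:
        # a zero-variation alignment is legal input; the regularizer then
        # dominates and the fit collapses to (near) zero couplings
        warnings.warn("effective number of sequences is 1; couplings are "
                      "regularization-dominated", RuntimeWarning)

    D = Lk * Q
    # dense one-hot design matrix; D ~ 1e3 keeps this comfortably in memory
    Xoh = np.zeros((N, D))
    rows = np.repeat(np.arange(N), Lk)
    cols = ((np.arange(Lk) * Q)[None, :] + X).ravel()  # observed-state columns
    Xoh[rows, cols] = 1.0
    w_rep = np.repeat(w, Lk)

    # parameters: fields (Lk*Q) + upper-triangle coupling blocks only; the
    # full symmetric matrix is reassembled per evaluation
    iu, ju = np.triu_indices(Lk, k=1)
    n_blocks = iu.size
    upper_rows = (iu[:, None, None] * Q + np.arange(Q)[None, :, None])
    upper_cols = (ju[:, None, None] * Q + np.arange(Q)[None, None, :])
    upper_rows = np.broadcast_to(upper_rows, (n_blocks, Q, Q)).ravel()
    upper_cols = np.broadcast_to(upper_cols, (n_blocks, Q, Q)).ravel()

    def expand(jvec):
        J = np.zeros((D, D))
        J[upper_rows, upper_cols] = jvec
        J[upper_cols, upper_rows] = jvec
        return J

    def objective(theta):
        h = theta[:D]
        jvec = theta[D:]
        J = expand(jvec)
        Z = (Xoh @ J + h).reshape(N, Lk, Q)  # site-wise conditional logits
        Zmax = Z.max(axis=2, keepdims=True)
        expZ = np.exp(Z - Zmax)
        S = expZ.sum(axis=2)
        lse = Zmax[:, :, 0] + np.log(S)
        picked = np.take_along_axis(Z, X[:, :, None], axis=2)[:, :, 0]
        nll = float(np.sum(w[:, None] * (lse - picked)))
        R = (expZ / S[:, :, None]).reshape(N, D) * w[:, None]
        R[rows, cols] -= w_rep  # observed-state part of the residual
        gJ_full = Xoh.T @ R
        # d/dJ_upper collects both symmetric appearances of each block
        gj = gJ_full[upper_rows, upper_cols] + gJ_full[upper_cols, upper_rows]
        gj += 2.0 * lambda_J * jvec
        gh = R.sum(axis=0) + 2.0 * lambda_h * h
        penalty = lambda_h * float(h @ h) + lambda_J * float(jvec @ jvec)
        return nll + penalty, np.concatenate([gh, gj])

    theta0 = np.zeros(D + n_blocks * Q * Q)
    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxcor": 6, "gtol": gtol, "ftol": 1e-9},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"pseudolikelihood fit stopped before convergence "
            f"({res.message!r} after {res.nit} iterations)",
            RuntimeWarning,
        )
    h_k = res.x[:D].reshape(Lk, Q)
    J_k = expand(res.x[D:])

    L = wmsa.length
    J = np.zeros((L, Q, L, Q))
    h = np.zeros((L, Q))
    h[keep] = h_k
    Jk4 = J_k.reshape(Lk, Q, Lk, Q)
    J[np.ix_(keep, range(Q), keep, range(Q))] = Jk4
    return PlmResult(J=J, h=h, converged=converged, n_iter=int(res.nit),
                     lambda_h=lambda_h, lambda_J=lambda_J)


# ---------------------------------------------------------------------------
# score extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPrediction:
    """A ranked covarying residue pair (1-based reference numbering, i < j)."""

    i: int
    j: int
    raw_score: float
    apc_score: float
    scaled_score: float
    rank: int


def _frobenius_scores(J: np.ndarray) -> np.ndarray:
    """Gauge-fixed Frobenius norms of the 20x20 (gap-excluded) blocks."""
    L = J.shape[0]
    B = J[:, :GAP, :, :GAP]  # L x 20 x L x 20
    # zero-sum gauge per block before taking the norm
    B = (B
         - B.mean(axis=1, keepdims=True)
         - B.mean(axis=3, keepdims=True)
         + B.mean(axis=(1, 3), keepdims=True))
    F = np.sqrt((B ** 2).sum(axis=(1, 3)))
    np.fill_diagonal(F, 0.0)
    return F


def scale_scores(apc_values: np.ndarray, shrink_z: float = 2.0) -> np.ndarray:
    """Noise-thresholded, mean-normalized score scale.

    APC-corrected scores within ``shrink_z`` robust standard deviations
    (1.4826 x median absolute deviation) of zero are estimation noise and
    collapse to zero; the rest are shifted down by that floor and divided by
    the mean of the surviving positive scores, which therefore average 1.
    The transform is monotone, so rankings by scaled and by APC score agree
    wherever the scaled score distinguishes pairs.
    """
    apc = np.asarray(apc_values, dtype=float)
    if apc.size == 0:
        return apc
    sigma = 1.4826 * float(np.median(np.abs(apc - np.median(apc))))
    floor = shrink_z * sigma
    shrunk = np.sign(apc) * np.maximum(np.abs(apc) - floor, 0.0)
    pos = shrunk[shrunk > 0]
    return shrunk / pos.mean() if pos.size else shrunk


def _rank_pairs(pairs: list[tuple[int, int, float, float]]) -> list[ContactPrediction]:
    """Shared ranking: scale, sort by (scaled desc, apc desc, (i, j))."""
    if not pairs:
        return []
    scaled = scale_scores(np.array([p[3] for p in pairs]))
    scored = sorted(
        [(ri, rj, r, a, s) for (ri, rj, r, a), s in zip(pairs, scaled)],
        key=lambda t: (-t[4], -t[3], t[0], t[1]),
    )
    return [
        ContactPrediction(i=ri, j=rj, raw_score=float(r), apc_score=float(a),
                          scaled_score=float(s), rank=k + 1)
        for k, (ri, rj, r, a, s) in enumerate(scored)
    ]


def coupling_scores(
    J: np.ndarray,
    min_separation: int = 5,
    ref_positions: np.ndarray | None = None,
    masked: np.ndarray | None = None,
) -> list[ContactPrediction]:
    """Rank residue pairs by coupling strength.

    raw = Frobenius norm of the gauge-fixed 20 x 20 coupling block;
    apc = raw after average-product correction; scaled = apc after noise
    thresholding and positive-mean normalization (see :func:`scale_scores`).
    Pairs closer than ``min_separation`` in reference numbering are
    suppressed.  Sorted by scaled then APC score descending, remaining ties
    broken by (i, j).
    """
    L = J.shape[0]
    if not np.allclose(J, np.transpose(J, (2, 3, 0, 1)), atol=1e-8):
        raise ValueError("J must be symmetric in (i,a) <-> (j,b)")
    raw = _frobenius_scores(J)
    if masked is not None:
        raw[masked, :] = 0.0
        raw[:, masked] = 0.0
    apc = apc_correct(raw)
    if ref_positions is None:
        ref_positions = np.arange(1, L + 1)

    pairs = []
    for i in range(L):
        if masked is not None and masked[i]:
            continue
        for j in range(i + 1, L):
            if masked is not None and masked[j]:
                continue
            ri, rj = int(ref_positions[i]), int(ref_positions[j])
            if ri < 0 or rj < 0 or abs(rj - ri) < min_separation:
                continue
            pairs.append((ri, rj, raw[i, j], apc[i, j]))
    return _rank_pairs(pairs)


def contacts_to_frame(contacts: Iterable[ContactPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"i": c.i, "j": c.j, "raw": c.raw_score, "apc": c.apc_score,
          "scaled": c.scaled_score, "rank": c.rank} for c in contacts],
        columns=["i", "j", "raw", "apc", "scaled", "rank"],
    )


def predict_contacts(
    msa: Sequence[str] | np.ndarray,
    method: str = "plm",
    id_threshold: float = 0.8,
    min_separation: int = 5,
    **fit_kwargs,
) -> list[ContactPrediction]:
    """Convenience pipeline: weights -> fit -> ranked contact predictions."""
    wmsa = msa_weights(msa, id_threshold=id_threshold)
    if method == "plm":
        fit = plm_fit(wmsa, **fit_kwargs)
        return coupling_scores(fit.J, min_separation=min_separation,
                               ref_positions=wmsa.ref_positions, masked=wmsa.masked)
    if method == "mi":
        scores = mi_apc(wmsa)
        L = scores.shape[0]
        pairs = []
        for i in range(L):
            if wmsa.masked[i]:
                continue
            for j in range(i + 1, L):
                if wmsa.masked[j]:
                    continue
                ri, rj = int(wmsa.ref_positions[i]), int(wmsa.ref_positions[j])
                if ri < 0 or rj < 0 or abs(rj - ri) < min_separation:
                    continue
                pairs.append((ri, rj, abs(scores[i, j]), scores[i, j]))
        return _rank_pairs(pairs)
    raise ValueError(f"method must be 'plm' or 'mi', got {method!r}")
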