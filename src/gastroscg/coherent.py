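"""Coherent ensemble averaging of cardiac cycles.

A 30-s acquisition yields a few dozen cardiac cycles.  Averaging the
mutually correlated ("coherent") subset of them boosts the SNR of the
mean cycle by roughly sqrt(N) while rejecting beats disturbed by growls,
gastric sounds or movement.  The chain is:

1. equalize cycle lengths to the median duration (zero-padding shorter
   cycles, truncating longer ones);
2. for accelerometer cycles, independently phase-correct the S1 and S2
   sub-windows — valve-sound latencies vary beat to beat with preload,
   afterload and inotropy, independently of the R peak;
3. keep the dominant group of cycles whose normalized cross-correlation
   with the best-centered template exceeds 0.6;
4. for accelerometer cycles (which must keep physical amplitude and so
   cannot be normalized), drop cycles whose energy lies more than three
   scaled median absolute deviations from the median;
5. average the survivors sample-wise.

All correlations are zero-normalized and evaluated on the non-padded
support only, so zero padding cannot inflate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import mad_outlier_mask
from .qrs import CycleSet

__all__ = [
    "CoherentMean", "GroupResult",
    "pad_cycles", "dominant_group", "phase_align_acc",
    "remove_outlier_cycles", "coherent_mean", "average_cycleset",
]


@dataclass
class CoherentMean:
    channel_id: str
    mean_cycle: np.ndarray
    member_idx: np.ndarray
    coherent_fraction: float          # % of cycles retained
    mean_intercycle_r: float          # mean pairwise correlation of members
    phase_shifts: list = field(default_factory=list)  # (s1_lag, s2_lag) s
    rate: float = 0.0
    r_offset: float = 0.0             # R time within the cycle, s
    aligned_cycles: np.ndarray | None = None
    valid_len: int = 0

    @property
    def n_coherent(self) -> int:
        return int(self.member_idx.size)


@dataclass
class GroupResult:
    template_idx: int
    members: np.ndarray    # indices of cycles correlated > rho with template
    lags: np.ndarray       # alignment lag (samples) per cycle vs template
    corrs: np.ndarray      # best-lag correlation per cycle vs template


def pad_cycles(cs: CycleSet) -> tuple[np.ndarray, np.ndarray]:
    """Equalize cycle lengths to the median cycle duration.

    Returns the (n_cycles, median_len) matrix and the per-cycle valid
    (non-padded) length.  Shorter cycles are zero-padded at the end,
    longer ones truncated at the median length.
    """
    if len(cs) < 1:
        raise ValueError("no cycles to pad")
    lengths = cs.lengths()
    m = int(round(float(np.median(lengths))))
    out = np.zeros((len(cs), m))
    valid = np.minimum(lengths, m)
    for i, c in enumerate(cs.cycles):
        out[i, : valid[i]] = c[:m]
    return out, valid


def _zncc(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-normalized correlation of two equal-length segments."""
    if x.size < 2:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    return float((xc @ yc) / den) if den > 0 else 0.0


def _pairwise_lagged_corr(C: np.ndarray, V: np.ndarray,
                          lags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best zero-normalized correlation over lags for every cycle pair.

    ``corr[i, j]`` uses cycle i shifted by ``lag[i, j]`` samples against
    cycle j, statistics restricted to the overlap of valid supports.
    """
    K, m = C.shape
    best = np.full((K, K), -np.inf)
    best_lag = np.zeros((K, K), dtype=int)
    CV = C * V
    for lag in lags:
        if lag >= 0:
            Cs = np.zeros_like(C); Vs = np.zeros_like(V)
            Cs[:, : m - lag] = C[:, lag:]
            Vs[:, : m - lag] = V[:, lag:]
        else:
            Cs = np.zeros_like(C); Vs = np.zeros_like(V)
            Cs[:, -lag:] = C[:, :lag]
            Vs[:, -lag:] = V[:, :lag]
        CsVs = Cs * Vs
        n = Vs @ V.T
        sx = CsVs @ V.T
        sy = Vs @ CV.T
        sxx = (CsVs * Cs) @ V.T
        syy = Vs @ (CV * C).T
        sxy = CsVs @ CV.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / n
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            r = cov / np.sqrt(vx * vy)
        r = np.where(np.isfinite(r) & (n >= 2), r, -np.inf)
        upd = r > best
        best[upd] = r[upd]
        best_lag[upd] = lag
    return best, best_lag


def dominant_group(cycles: np.ndarray, rho: float = 0.6,
                   max_lag: int = 10, valid: np.ndarray | None = None,
                   template_idx: int | None = None) -> GroupResult:
    """Find the dominant group of mutually correlated cycles.

    The template is the cycle maximizing its median best-lag correlation
    to all others; members are the cycles whose best-lag correlation
    with the template exceeds ``rho``.  ``max_lag`` bounds the alignment
    search (samples) around the R-synchronous position.
    """
    C = np.asarray(cycles, dtype=float)
    K, m = C.shape
    if valid is None:
        valid = np.full(K, m, dtype=int)
    V = np.zeros_like(C)
    for i, v in enumerate(valid):
        V[i, :v] = 1.0
    if K == 1:
        return GroupResult(0, np.array([0]), np.zeros(1, int), np.ones(1))
    lags = np.arange(-max_lag, max_lag + 1)
    best, best_lag = _pairwise_lagged_corr(C, V, lags)
    if template_idx is None:
        med = np.empty(K)
        for i in range(K):
            others = np.delete(best[i], i)
            med[i] = np.median(others)
        template_idx = int(np.argmax(med))
    # lag convention: shift cycle j by lags[j] to align it with the template
    corrs = best[:, template_idx].copy()
    lagv = -best_lag[:, template_idx]
    corrs[template_idx] = 1.0
    lagv[template_idx] = 0
    members = np.flatnonzero(corrs > rho)
    if template_idx not in members:
        members = np.sort(np.append(members, template_idx))
    return GroupResult(template_idx, members, lagv, corrs)


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift left by ``lag`` samples (content at index k+lag moves to k)."""
    out = np.zeros_like(x)
    if lag >= 0:
        out[: x.size - lag] = x[lag:]
    else:
        out[-lag:] = x[:lag]
    return out


def phase_align_acc(cycles: np.ndarray, template_idx: int,
                    s1_win: tuple[int, int], s2_win: tuple[int, int],
                    max_lag: int) -> tuple[np.ndarray, list]:
    """Independent S1/S2 phase correction of accelerometer cycles.

    For each cycle, the S1 and S2 sub-windows are shifted by the lag
    (bounded by ``max_lag`` samples) maximizing their correlation with
    the template's corresponding sub-window.  A shift is only kept when
    it does not lower the cycle's full-length correlation with the
    template, so the mean inter-cycle correlation cannot decrease.
    """
    C = np.asarray(cycles, dtype=float)
    K, m = C.shape
    tmpl = C[template_idx]
    aligned = C.copy()
    shifts = []
    for i in range(K):
        cyc = C[i]
        cur = cyc.copy()
        cur_r = _zncc(cur, tmpl)
        lag_out = []
        for (a, b) in (s1_win, s2_win):
            a, b = max(0, a), min(m, b)
            ref = tmpl[a:b]
            if b - a < 2 or not np.any(ref) or not np.any(cyc[a:b]):
                lag_out.append(0)
                continue
            best_lag, best_r = 0, _zncc(cyc[a:b], ref)
            for lag in range(-max_lag, max_lag + 1):
                lo, hi = a + lag, b + lag
                seg = (cyc[lo:hi] if 0 <= lo and hi <= m
                       else _shift(cyc, lag)[a:b])
                r = _zncc(seg, ref)
                if r > best_r:
                    best_lag, best_r = lag, r
            cand = cur.copy()
            cand[a:b] = (cyc[a + best_lag: b + best_lag]
                         if 0 <= a + best_lag and b + best_lag <= m
                         else _shift(cyc, best_lag)[a:b])
            cand_r = _zncc(cand, tmpl)
            if cand_r >= cur_r:
                cur, cur_r = cand, cand_r
                lag_out.append(best_lag)
            else:
                lag_out.append(0)
        aligned[i] = cur
        shifts.append(tuple(lag_out))
    return aligned, shifts


def remove_outlier_cycles(cycles: np.ndarray,
                          idx: np.ndarray | None = None) -> np.ndarray:
    """Indices of cycles whose energy is not a scaled-MAD outlier."""
    C = np.asarray(cycles, dtype=float)
    if idx is None:
        idx = np.arange(C.shape[0])
    if idx.size < 3:
        return idx
    energy = np.sum(C[idx] * C[idx], axis=1)
    return idx[~mad_outlier_mask(energy)]


def _mean_pairwise_r(C: np.ndarray) -> float:
    K = C.shape[0]
    if K < 2:
        return 1.0
    Z = C - C.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(Z * Z, axis=1))
    ok = norms > 0
    if ok.sum() < 2:
        return 0.0
    Zn = Z[ok] / norms[ok, None]
    R = Zn @ Zn.T
    iu = np.triu_indices(ok.sum(), k=1)
    return float(np.mean(R[iu]))


def coherent_mean(aligned: np.ndarray, members: np.ndarray,
                  channel_id: str = "", rate: float = 0.0,
                  r_offset: float = 0.0, phase_shifts: list | None = None,
                  n_total: int | None = None,
                  valid_len: int | None = None) -> CoherentMean:
    """Sample-wise mean over the coherent member cycles."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("no coherent members: nothing to average")
    A = np.asarray(aligned, dtype=float)
    n_total = A.shape[0] if n_total is None else n_total
    mean = A[members].mean(axis=0)
    return CoherentMean(
        channel_id=channel_id,
        mean_cycle=mean,
        member_idx=members,
        coherent_fraction=100.0 * members.size / max(n_total, 1),
        mean_intercycle_r=_mean_pairwise_r(A[members]),
        phase_shifts=phase_shifts or [],
        rate=rate,
        r_offset=r_offset,
        aligned_cycles=A,
        valid_len=int(valid_len) if valid_len else A.shape[1],
    )


def average_cycleset(cs: CycleSet, *, is_acc: bool, rho: float = 0.6,
                     max_lag_s: float = 0.05,
                     s1_frac: float = 0.45) -> CoherentMean | None:
    """Full coherent-averaging chain for one channel's cycle set.

    ECG cycles (already normalized upstream) are padded, gated on the
    0.6-correlation dominant group and averaged.  Accelerometer cycles
    additionally get S1/S2 phase correction before the group gate and
    energy-based outlier rejection after it.  Returns ``None`` when no
    coherent member survives (handled by the stage-1 quality gate).
    """
    if len(cs) == 0:
        return None
    C, valid = pad_cycles(cs)
    m = C.shape[1]
    max_lag = max(1, int(round(max_lag_s * cs.rate)))
    r_samp = int(round(cs.r_offset * cs.rate))
    shifts: list = []
    if is_acc and len(cs) >= 2:
        g0 = dominant_group(C, rho=rho, max_lag=max_lag, valid=valid)
        rr = m - r_samp  # cycle length past R ~= one median R-R
        s1_win = (r_samp, r_samp + int(round(s1_frac * rr)))
        s2_win = (s1_win[1], m)
        C, shifts = phase_align_acc(C, g0.template_idx, s1_win, s2_win,
                                    max_lag)
        g = dominant_group(C, rho=rho, max_lag=max_lag, valid=valid,
                           template_idx=g0.template_idx)
    else:
        g = dominant_group(C, rho=rho, max_lag=max_lag, valid=valid)
    # apply residual global alignment lags from the group search
    A = np.vstack([_shift(C[i], int(g.lags[i])) for i in range(C.shape[0])])
    members = g.members
    if is_acc:
        members = remove_outlier_cycles(A, members)
    if members.size == 0:
        return None
    fs = cs.rate
    shift_s = ([(s1 / fs, s2 / fs) for (s1, s2) in shifts]
               if shifts else [])
    return coherent_mean(A, members, channel_id=cs.channel_id, rate=cs.rate,
                         r_offset=cs.r_offset, phase_shifts=shift_s,
                         n_total=len(cs), valid_len=int(valid[members].min()))
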