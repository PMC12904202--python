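"""Nonnegative tensor factorization (NTF) of evoked-release trains.

A cohort's quantal contents form a synapse x frequency x stimulus
tensor ``V[s, f, j]``.  NTF decomposes it into a small number of
kinetic components,

    V[s, f, j]  ~  sum_c  L[s, c] * W[c, f, j],

where the loading ``L[s, c]`` is the number of vesicles synapse ``s``
holds in priming state ``c`` before stimulation and the shared
signature ``W[c, f, j]`` is the fraction of that pool released at
stimulus ``j`` of an ``f``-Hz train.  With two components the loadings
are the tightly (M_TS) and loosely (M_LS) docked pools; sharing the
signatures across synapses enforces a common initial fusion
probability within a cohort, which is then read out as the slope of
the regression of the initial quantal content m_1 on M_TS through the
origin.

The factorization is alternating nonnegative least squares on the
masked entries (not every synapse is recorded at every frequency);
each block update is an exact minimizer, so the objective is
nonincreasing.  Scale indeterminacy is resolved by rescaling each
component so that its most depleting frequency releases the whole
pool (max_f sum_j W[c, f, j] = 1), with the loadings absorbing the
factor; the component with the larger first-stimulus release share at
the highest frequency is labeled TS.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls

from .quantal import PairedMeasurements, QuantalTrain, regression_through_origin

__all__ = ["TrainTensor", "NTFResult", "ntf_decompose", "pfusion_from_loadings"]


@dataclass
class TrainTensor:
    """Synapse x frequency x stimulus tensor of quantal contents."""

    values: np.ndarray            # (S, F, J), >= 0 where mask is True
    mask: np.ndarray              # (S, F, J) bool; False = not recorded
    frequencies: np.ndarray       # (F,) Hz
    synapse_ids: Optional[list] = None
    genotype: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.values.ndim != 3 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be (S, F, J) arrays")
        if self.frequencies.size != self.values.shape[1]:
            raise ValueError("frequencies must match axis 1")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("quantal contents must be nonnegative")
        if self.synapse_ids is None:
            self.synapse_ids = [f"syn{i}" for i in range(self.values.shape[0])]

    @classmethod
    def from_trains(cls, trains: Sequence[QuantalTrain],
                    genotype: str = "synthetic") -> "TrainTensor":
        """Stack QuantalTrains (grouped by synapse_id and f_stim)."""
        syn_ids = sorted({t.synapse_id for t in trains})
        freqs = sorted({t.f_stim for t in trains})
        J = max(len(t) for t in trains)
        S, F = len(syn_ids), len(freqs)
        values = np.zeros((S, F, J))
        mask = np.zeros((S, F, J), bool)
        for t in trains:
            s = syn_ids.index(t.synapse_id)
            f = freqs.index(t.f_stim)
            values[s, f, : len(t)] = t.m
            mask[s, f, : len(t)] = True
        return cls(values=values, mask=mask, frequencies=np.array(freqs),
                   synapse_ids=syn_ids, genotype=genotype)

    @classmethod
    def from_long(cls, df, genotype: str = "synthetic") -> "TrainTensor":
        """Build from a long-format table with columns synapse_id,
        f_stim_hz, stim_index (1-based) and m."""
        need = {"synapse_id", "f_stim_hz", "stim_index", "m"}
        if not need.issubset(df.columns):
            raise ValueError(f"long table needs columns {sorted(need)}")
        syn_ids = sorted(df["synapse_id"].unique())
        freqs = sorted(df["f_stim_hz"].unique())
        J = int(df["stim_index"].max())
        values = np.zeros((len(syn_ids), len(freqs), J))
        mask = np.zeros_like(values, bool)
        s_idx = {s: i for i, s in enumerate(syn_ids)}
        f_idx = {f: i for i, f in enumerate(freqs)}
        for row in df.itertuples(index=False):
            s, f, j = s_idx[row.synapse_id], f_idx[row.f_stim_hz], int(row.stim_index) - 1
            values[s, f, j] = row.m
            mask[s, f, j] = True
        return cls(values=values, mask=mask, frequencies=np.array(freqs, float),
                   synapse_ids=list(syn_ids), genotype=genotype)

    @property
    def m1(self) -> np.ndarray:
        """Per-synapse initial quantal content, averaged over the
        frequencies at which the synapse was recorded."""
        first = self.values[:, :, 0]
        avail = self.mask[:, :, 0]
        with np.errstate(invalid="ignore"):
            out = np.where(avail.any(1),
                           (first * avail).sum(1) / np.maximum(avail.sum(1), 1),
                           np.nan)
        return out


@dataclass
class NTFResult:
    """Labeled nonnegative decomposition of a train tensor."""

    loadings: np.ndarray          # (S, C), component order: TS, LS[, recruit]
    signatures: np.ndarray        # (C, F, J)
    component_labels: Tuple[str, ...]
    residual: float               # relative masked Frobenius error
    n_iter: int
    converged: bool
    seed: int
    objective_history: np.ndarray
    p_fusion: Optional[float] = None
    p_fusion_se: Optional[float] = None

    @property
    def M_TS(self) -> np.ndarray:
        return self.loadings[:, self.component_labels.index("TS")]

    @property
    def M_LS(self) -> np.ndarray:
        return self.loadings[:, self.component_labels.index("LS")]

    @property
    def f_ts(self) -> np.ndarray:
        """Per-synapse tight-state fraction M_TS / (M_TS + M_LS)."""
        denom = self.M_TS + self.M_LS
        return np.where(denom > 0, self.M_TS / np.maximum(denom, 1e-300), 0.0)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("sc,cfj->sfj", self.loadings, self.signatures)


def _masked_objective(V, mask, L, W2) -> float:
    rec = L @ W2
    num = np.sum((V - rec)[mask] ** 2)
    den = np.sum(V[mask] ** 2)
    return np.sqrt(num / den) if den > 0 else 0.0


def _update_loadings(V, mask, W2, C):
    S = V.shape[0]
    L = np.zeros((S, C))
    for s in range(S):
        cols = mask[s]
        if not cols.any():
            continue
        A = W2[:, cols].T
        L[s], _ = nnls(A, V[s, cols])
    return L


def _ridge_nnls(A, b, lam):
    if lam > 0:
        n = A.shape[1]
        A = np.vstack([A, math.sqrt(lam) * np.eye(n)])
        b = np.concatenate([b, np.zeros(n)])
    return nnls(A, b)[0]


def _update_signatures(V, mask, L, C, J, F, constrain_last: bool,
                       delayed_onset: bool, lam: float):
    K = F * J
    W2 = np.zeros((C, K))
    if not constrain_last:
        for k in range(K):
            rows = mask[:, k]
            if not rows.any():
                continue
            if delayed_onset and k % J == 0:
                # only the pre-stimulus TS pool releases at stimulus 1
                W2[0, k] = _ridge_nnls(L[rows, :1], V[rows, k], lam)[0]
            else:
                W2[:, k] = _ridge_nnls(L[rows], V[rows, k], lam)
        return W2
    # last component's signature constrained nondecreasing in j within
    # each frequency: parameterize it by nonnegative increments u with
    # W[C-1, f, j] = sum_{i<=j} u[f, i] and solve one joint NNLS per
    # frequency (exact block minimizer, keeps the objective monotone).
    # Under the delayed-onset constraint, non-TS components release
    # nothing at stimulus 1 (their unknowns for j = 1 are dropped).
    cum = np.tril(np.ones((J, J)))
    for f in range(F):
        ks = slice(f * J, (f + 1) * J)
        sub_mask = mask[:, ks]
        rows, cols = np.nonzero(sub_mask)
        if rows.size == 0:
            continue
        # column index map per component, skipping frozen-zero unknowns
        keep = []
        for c in range(C):
            first = 1 if (delayed_onset and c > 0) else 0
            keep.append(np.arange(first, J))
        offsets = np.cumsum([0] + [k.size for k in keep])
        A = np.zeros((rows.size, offsets[-1]))
        for c in range(C - 1):
            pos = cols - keep[c][0]
            ok = pos >= 0
            A[np.flatnonzero(ok), offsets[c] + pos[ok]] = L[rows[ok], c]
        cum_c = cum[:, keep[C - 1]]
        A[:, offsets[C - 1]:] = L[rows, C - 1][:, None] * cum_c[cols]
        b = V[:, ks][sub_mask]
        w = _ridge_nnls(A, b, lam)
        for c in range(C - 1):
            W2[c, ks][keep[c]] = w[offsets[c]:offsets[c + 1]]
        W2[C - 1, ks] = cum_c @ w[offsets[C - 1]:]
    return W2


def _demix(L: np.ndarray, W2: np.ndarray, *, rmse: float = 0.0,
           z: float = 0.5, eps: float = 0.05,
           max_sweeps: int = 50) -> Tuple[np.ndarray, np.ndarray]:
    """Reduce each signature to its irreducible part.

    A masked nonnegative factorization retains a rotational freedom:
    component ``c`` can carry a nonnegative multiple of component
    ``d``'s signature, with the loadings compensating, without
    changing the fit.  Sweeping all ordered pairs, the largest such
    multiple keeping ``W_c`` nonnegative is transferred out
    (``W_c -= alpha * W_d``, ``L_d += alpha * L_c``), which preserves
    the reconstruction and terminates at the extreme factorization in
    which every signature has a zero where each other signature is
    positive.  When the generating components are themselves
    irreducible in this sense — release time courses of distinct
    priming states deplete at distinct stimuli — this is the
    generating solution.

    On noisy fits the entries of a signature never reach zero exactly;
    ``z`` standard errors of the signature estimate (derived from the
    fit RMSE ``rmse`` and the loading column norm) are granted as
    head-room, and the subtracted signature is clipped at zero.  With
    ``rmse = 0`` the rule is the exact nonnegativity-preserving one.
    """
    L = L.copy()
    W2 = W2.copy()
    C = W2.shape[0]
    for _ in range(max_sweeps):
        changed = False
        for c in range(C):
            se_c = z * rmse / max(float(np.linalg.norm(L[:, c])), 1e-300)
            for d in range(C):
                if c == d or W2[d].max() <= 0:
                    continue
                pos = W2[d] > eps * W2[d].max()
                alpha = float(np.min((W2[c][pos] + se_c) / W2[d][pos]))
                if alpha > 1e-6:
                    W2[c] = np.maximum(W2[c] - alpha * W2[d], 0.0)
                    L[:, d] += alpha * L[:, c]
                    changed = True
        if not changed:
            break
    return L, W2


def ntf_decompose(tensor: TrainTensor, n_components: int = 2, *,
                  n_restarts: int = 10, seed: int = 0, tol: float = 1e-7,
                  max_iter: int = 500,
                  constrain_recruitment: bool = True,
                  delayed_onset: bool = True,
                  demix: bool = True,
                  demix_z: float = 0.5,
                  ridge: float = 0.0) -> NTFResult:
    """Masked alternating-NNLS factorization of a train tensor.

    ``n_components``: 2 (TS, LS) or 3 (TS, LS plus a recruitment
    component whose release signature is constrained nondecreasing in
    the stimulus index, absorbing steady-state replenishment); 1 is
    accepted for rank checks.  With ``delayed_onset`` (the priming
    interpretation) only the TS component may release at stimulus 1:
    vesicles loosely docked or recruited during the train need at
    least one inter-stimulus interval to become fusion competent.
    This pins the otherwise scale/rotation-ambiguous split between
    components; disable it to factorize generic tensors.  The best of
    ``n_restarts`` random initializations (sub-seeds derived from
    ``seed``) is kept, ties broken by lowest residual then lowest
    sub-seed.  ``demix`` resolves the residual rotational ambiguity
    between components (see :func:`_demix`) without changing the fit.
    ``ridge`` adds a small L2 penalty (relative to the loading scale)
    to the signature updates; because the mixing ambiguity between
    components is one-sided, the penalty steers flat directions of
    the objective toward the irreducible factorization on noisy data
    while leaving well-determined directions essentially untouched.
    Set ``ridge=0`` for exact unpenalized ALS (strictly nonincreasing
    objective).  The estimated common fusion probability (slope of
    m_1 on M_TS through the origin) is attached for ranks >= 2.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if tol <= 0:
        raise ValueError("tol must be positive")
    V3, mask3 = tensor.values, tensor.mask
    S, F, J = V3.shape
    if not mask3.any() or np.all(V3[mask3] == 0):
        raise ValueError("degenerate tensor: no observed nonzero entries")
    V = V3.reshape(S, F * J)
    mask = mask3.reshape(S, F * J)
    C = n_components
    constrain_last = constrain_recruitment and C == 3
    scale = float(np.mean(V[mask]))

    best = None
    root = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 root.spawn(n_restarts)]
    for sub in sub_seeds:
        rng = np.random.default_rng(sub)
        W2 = rng.uniform(0.1, 1.0, size=(C, F * J))
        L = _update_loadings(V, mask, W2, C) * scale
        history = []
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            lam = ridge * float(np.mean(np.sum(L * L, axis=1)))
            W2 = _update_signatures(V, mask, L, C, J, F, constrain_last,
                                    delayed_onset, lam)
            L = _update_loadings(V, mask, W2, C)
            if demix:
                # exact fit-preserving de-mix accelerates convergence
                # along the otherwise flat mixing direction
                L, W2 = _demix(L, W2, rmse=0.0, eps=1e-12)
            obj = _masked_objective(V, mask, L, W2)
            if ridge == 0 and history and obj > history[-1] + 1e-12:
                raise AssertionError("ALS objective increased")
            history.append(obj)
            if prev - obj < tol * max(prev, 1e-12):
                converged = True
                break
            prev = obj
        cand = (history[-1], sub, L, W2, it, converged, np.asarray(history))
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    residual, sub, L, W2, n_iter, converged, history = best

    if demix:
        rec = L @ W2
        n_obs = int(mask.sum())
        rmse = float(np.sqrt(np.sum((V - rec)[mask] ** 2) / n_obs))
        L, W2 = _demix(L, W2, rmse=rmse, z=demix_z)
    W = W2.reshape(C, F, J)
    # resolve scale: complete depletion at the most depleting frequency
    for c in range(C):
        d = W[c].sum(axis=1).max()
        if d > 0:
            W[c] /= d
            L[:, c] *= d
    # label: TS releases the largest first-stimulus fraction at the
    # highest frequency (with delayed onset, that is component 0 by
    # construction); the recruitment component, when present and
    # constrained, stays last
    f_max = int(np.argmax(tensor.frequencies))
    if delayed_onset:
        order = list(range(C))
    else:
        first_share = W[:, f_max, 0]
        order = list(np.argsort(-first_share))
        if C == 3:
            rest = order[1:]
            rest.sort(key=lambda c: -L[:, c].sum())
            order = [order[0]] + rest
    L = L[:, order]
    W = W[order]
    labels = ("TS",) if C == 1 else ("TS", "LS") if C == 2 \
        else ("TS", "LS", "recruitment")

    result = NTFResult(loadings=L, signatures=W, component_labels=labels,
                       residual=residual, n_iter=n_iter, converged=converged,
                       seed=sub, objective_history=history)
    if C >= 2:
        m1 = tensor.m1
        ok = np.isfinite(m1) & (result.M_TS >= 0)
        if ok.sum() >= 2 and np.any(result.M_TS[ok] > 0):
            slope, se = pfusion_from_loadings(m1[ok], result.M_TS[ok])
            result.p_fusion = slope
            result.p_fusion_se = se
    return result


def pfusion_from_loadings(m1: Sequence[float],
                          M_TS: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Common fusion probability as the slope of the regression of the
    initial quantal content m_1 on the tight-state pool M_TS through
    the origin.  Returns (slope, se)."""
    m1 = np.asarray(m1, dtype=float)
    M = np.asarray(M_TS, dtype=float)
    if m1.size < 2:
        raise ValueError("need >= 2 synapses")
    return regression_through_origin(PairedMeasurements(x=M, y=m1,
                                                        label="m1 vs M_TS"))
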