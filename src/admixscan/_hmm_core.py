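"""Low-level HMM recursions for two-way local-ancestry inference.

State space: the ordered pair of ancestry backgrounds of the two chromosome
copies, copy state 0 = African, 1 = European, pair index s = 2*c1 + c2.
Per copy, over a gap of d Morgans the background is kept with probability
stay = exp(-lambda*d) and otherwise redrawn from the stationary law
pi = (theta, 1-theta); chromosome starts are encoded as stay = 0, i.e. a
stationary draw. Genotypes emit as the sum of one Bernoulli(freq) draw per
copy, with the frequency chosen by the copy's background; missing genotypes
emit likelihood 1.

Two entry points:

* :func:`forward_backward_exact` - exact posterior marginals of the
  European-allele count, vectorized over individuals.
* ``sweep`` (numba-compiled when available, numpy fallback otherwise) - one
  MCMC iteration: forward-filter backward-sample ancestry paths plus the
  augmented draws (stationary redraw indicators, per-copy allele
  assignments) that make the theta / lambda / allele-frequency updates
  conjugate or cheap.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


def _emission_table(geno_j, pa, pe):
    """Emission probabilities (N, 4) for one marker, numpy path."""
    n = geno_j.shape[0]
    # per-copy variant prob by copy state: 0 -> pa, 1 -> pe
    p = np.array([pa, pe])
    em = np.empty((n, 4))
    for s in range(4):
        p1, p2 = p[s >> 1], p[s & 1]
        e0 = (1 - p1) * (1 - p2)
        e1 = p1 * (1 - p2) + (1 - p1) * p2
        e2 = p1 * p2
        em[:, s] = np.choose(np.clip(geno_j, 0, 2), [e0, e1, e2])
    em[geno_j < 0] = 1.0
    return em


def forward_backward_exact(geno, stay, theta, pA, pE):
    """Exact posterior over European-allele count per marker.

    Parameters
    ----------
    geno : (N, L) int array, variant counts with -1 for missing.
    stay : (L,) per-marker stay probability exp(-lambda*d); 0 at chromosome starts.
    theta : (N,) African proportion per individual.
    pA, pE : (L,) variant-allele frequencies in the two ancestral populations.

    Returns
    -------
    gamma : (N, L, 3) posterior P(EuropeanCount = 0, 1, 2) per individual x marker.
    """
    geno = np.asarray(geno)
    n, L = geno.shape
    theta = np.asarray(theta, float)
    pi = np.stack([theta, 1 - theta], axis=1)  # (N, 2)

    alphas = np.empty((L, n, 2, 2))
    # forward pass with per-step normalization
    a = None
    for j in range(L):
        em = _emission_table(geno[:, j], pA[j], pE[j]).reshape(n, 2, 2)
        if stay[j] == 0.0 or a is None:
            pred = pi[:, :, None] * pi[:, None, :]
        else:
            s = stay[j]
            # contract copy 1 then copy 2 using T = s*I + (1-s)*pi
            t1 = s * a + (1 - s) * pi[:, :, None] * a.sum(axis=1, keepdims=True)
            pred = s * t1 + (1 - s) * pi[:, None, :] * t1.sum(axis=2, keepdims=True)
        a = pred * em
        norm = a.sum(axis=(1, 2), keepdims=True)
        norm[norm == 0] = 1.0
        a = a / norm
        alphas[j] = a

    gamma = np.empty((n, L, 3))
    b = np.ones((n, 2, 2))
    for j in range(L - 1, -1, -1):
        post = alphas[j] * b
        post /= post.sum(axis=(1, 2), keepdims=True)
        # copy state 0 = African: European count = (c1==1) + (c2==1)
        gamma[:, j, 0] = post[:, 0, 0]
        gamma[:, j, 1] = post[:, 0, 1] + post[:, 1, 0]
        gamma[:, j, 2] = post[:, 1, 1]
        if j > 0:
            em = _emission_table(geno[:, j], pA[j], pE[j]).reshape(n, 2, 2)
            bb = em * b
            if stay[j] == 0.0:
                # chain restarts: message to the previous marker is a constant
                const = (pi[:, :, None] * pi[:, None, :] * bb).sum(axis=(1, 2))
                b = np.ones((n, 2, 2)) * const[:, None, None]
            else:
                s = stay[j]
                # backward contraction: b_prev[c] = sum_c' T[c,c'] bb[c']
                t1 = s * bb + (1 - s) * (pi[:, :, None] * bb).sum(axis=1, keepdims=True)
                b = s * t1 + (1 - s) * (pi[:, None, :] * t1).sum(axis=2, keepdims=True)
            norm = b.sum(axis=(1, 2), keepdims=True)
            norm[norm == 0] = 1.0
            b = b / norm
    return gamma


@njit(cache=True)
def _sweep_jit(geno, stay, is_start, theta, pA, pE, u, accumulate, nA_draw, n_draw, R, varA, totA, varE, totE, gamma_acc):  # pragma: no cover - compiled
    n, L = geno.shape
    alpha = np.empty((L, 4))
    ems = np.empty((L, 4))
    em = np.empty(4)
    w = np.empty(4)
    bwd = np.empty(4)
    bb = np.empty(4)
    st = np.empty(L, dtype=np.int8)
    for i in range(n):
        th = theta[i]
        pi0 = th
        pi1 = 1.0 - th
        # forward filter
        for j in range(L):
            g = geno[i, j]
            for s in range(4):
                p1 = pA[j] if (s >> 1) == 0 else pE[j]
                p2 = pA[j] if (s & 1) == 0 else pE[j]
                if g == 0:
                    em[s] = (1 - p1) * (1 - p2)
                elif g == 1:
                    em[s] = p1 * (1 - p2) + (1 - p1) * p2
                elif g == 2:
                    em[s] = p1 * p2
                else:
                    em[s] = 1.0
                ems[j, s] = em[s]
            if is_start[j]:
                w[0] = pi0 * pi0
                w[1] = pi0 * pi1
                w[2] = pi1 * pi0
                w[3] = pi1 * pi1
            else:
                sj = stay[j]
                a0 = alpha[j - 1, 0]
                a1 = alpha[j - 1, 1]
                a2 = alpha[j - 1, 2]
                a3 = alpha[j - 1, 3]
                # contract copy 1: t[c1', c2] = s*a[c1', c2] + (1-s)*pi[c1']*sum_c1 a[c1, c2]
                s0 = a0 + a2
                s1 = a1 + a3
                t0 = sj * a0 + (1 - sj) * pi0 * s0
                t1 = sj * a1 + (1 - sj) * pi0 * s1
                t2 = sj * a2 + (1 - sj) * pi1 * s0
                t3 = sj * a3 + (1 - sj) * pi1 * s1
                # contract copy 2
                r0 = t0 + t1
                r1 = t2 + t3
                w[0] = sj * t0 + (1 - sj) * pi0 * r0
                w[1] = sj * t1 + (1 - sj) * pi1 * r0
                w[2] = sj * t2 + (1 - sj) * pi0 * r1
                w[3] = sj * t3 + (1 - sj) * pi1 * r1
            tot = 0.0
            for s in range(4):
                w[s] *= em[s]
                tot += w[s]
            if tot <= 0.0:
                for s in range(4):
                    w[s] = 0.25
                tot = 1.0
            for s in range(4):
                alpha[j, s] = w[s] / tot
        # backward sample
        uu = u[i, L - 1, 0]
        c = 0.0
        s_next = 3
        for s in range(4):
            c += alpha[L - 1, s]
            if uu <= c:
                s_next = s
                break
        st[L - 1] = s_next
        for j in range(L - 2, -1, -1):
            sj = stay[j + 1]
            if is_start[j + 1]:
                for s in range(4):
                    w[s] = alpha[j, s]
            else:
                c1n = st[j + 1] >> 1
                c2n = st[j + 1] & 1
                pn1 = pi0 if c1n == 0 else pi1
                pn2 = pi0 if c2n == 0 else pi1
                for s in range(4):
                    t1v = (1 - sj) * pn1 + (sj if (s >> 1) == c1n else 0.0)
                    t2v = (1 - sj) * pn2 + (sj if (s & 1) == c2n else 0.0)
                    w[s] = alpha[j, s] * t1v * t2v
            tot = 0.0
            for s in range(4):
                tot += w[s]
            uu = u[i, j, 0] * tot
            c = 0.0
            pick = 3
            for s in range(4):
                c += w[s]
                if uu <= c:
                    pick = s
                    break
            st[j] = pick
        # augmented draws: stationary redraws, allele assignment, accumulation
        for j in range(L):
            c1 = st[j] >> 1
            c2 = st[j] & 1
            if is_start[j]:
                n_draw[i] += 2
                if c1 == 0:
                    nA_draw[i] += 1
                if c2 == 0:
                    nA_draw[i] += 1
            else:
                sj = stay[j]
                cp1 = st[j - 1] >> 1
                cp2 = st[j - 1] & 1
                # copy 1
                num = (1 - sj) * (pi0 if c1 == 0 else pi1)
                den = num + (sj if c1 == cp1 else 0.0)
                if den > 0 and u[i, j, 1] * den < num:
                    n_draw[i] += 1
                    R[j] += 1
                    if c1 == 0:
                        nA_draw[i] += 1
                # copy 2
                num = (1 - sj) * (pi0 if c2 == 0 else pi1)
                den = num + (sj if c2 == cp2 else 0.0)
                if den > 0 and u[i, j, 2] * den < num:
                    n_draw[i] += 1
                    R[j] += 1
                    if c2 == 0:
                        nA_draw[i] += 1
            g = geno[i, j]
            if g >= 0:
                p1 = pA[j] if c1 == 0 else pE[j]
                p2 = pA[j] if c2 == 0 else pE[j]
                if g == 0:
                    a1 = 0
                    a2 = 0
                elif g == 2:
                    a1 = 1
                    a2 = 1
                else:
                    w1 = p1 * (1 - p2)
                    w2 = (1 - p1) * p2
                    if w1 + w2 <= 0:
                        w1 = 0.5
                        w2 = 0.5
                    a1 = 1 if u[i, j, 3] * (w1 + w2) < w1 else 0
                    a2 = 1 - a1
                if c1 == 0:
                    totA[j] += 1
                    varA[j] += a1
                else:
                    totE[j] += 1
                    varE[j] += a1
                if c2 == 0:
                    totA[j] += 1
                    varA[j] += a2
                else:
                    totE[j] += 1
                    varE[j] += a2
        if accumulate:
            # Rao-Blackwellized accumulation: exact smoothing marginals given
            # the current parameter draw, not sampled-path indicators
            for s in range(4):
                bwd[s] = 0.25
            for j in range(L - 1, -1, -1):
                tot = 0.0
                for s in range(4):
                    w[s] = alpha[j, s] * bwd[s]
                    tot += w[s]
                gamma_acc[i, j, 0] += w[0] / tot
                gamma_acc[i, j, 1] += (w[1] + w[2]) / tot
                gamma_acc[i, j, 2] += w[3] / tot
                if j > 0:
                    for s in range(4):
                        bb[s] = ems[j, s] * bwd[s]
                    if is_start[j]:
                        const = (
                            pi0 * pi0 * bb[0]
                            + pi0 * pi1 * bb[1]
                            + pi1 * pi0 * bb[2]
                            + pi1 * pi1 * bb[3]
                        )
                        for s in range(4):
                            bwd[s] = const
                    else:
                        sj = stay[j]
                        m0 = pi0 * bb[0] + pi1 * bb[2]
                        m1 = pi0 * bb[1] + pi1 * bb[3]
                        t0 = sj * bb[0] + (1 - sj) * m0
                        t1 = sj * bb[1] + (1 - sj) * m1
                        t2 = sj * bb[2] + (1 - sj) * m0
                        t3 = sj * bb[3] + (1 - sj) * m1
                        n0 = pi0 * t0 + pi1 * t1
                        n1 = pi0 * t2 + pi1 * t3
                        bwd[0] = sj * t0 + (1 - sj) * n0
                        bwd[1] = sj * t1 + (1 - sj) * n0
                        bwd[2] = sj * t2 + (1 - sj) * n1
                        bwd[3] = sj * t3 + (1 - sj) * n1
                    totb = bwd[0] + bwd[1] + bwd[2] + bwd[3]
                    for s in range(4):
                        bwd[s] /= totb


def _sweep_numpy(geno, stay, is_start, theta, pA, pE, u, accumulate, nA_draw, n_draw, R, varA, totA, varE, totE, gamma_acc):
    """Vectorized reference implementation of one MCMC sweep.

    Consumes the identical uniform-variate array as the compiled kernel and
    produces bit-identical outputs; kept both as the no-numba fallback and as
    the equivalence oracle for the kernel.
    """
    n, L = geno.shape
    theta = np.asarray(theta, float)
    pi = np.stack([theta, 1 - theta], axis=1)

    alphas = np.empty((L, n, 2, 2))
    a = None
    for j in range(L):
        em = _emission_table(geno[:, j], pA[j], pE[j]).reshape(n, 2, 2)
        if is_start[j] or a is None:
            pred = pi[:, :, None] * pi[:, None, :]
        else:
            s = stay[j]
            t1 = s * a + (1 - s) * pi[:, :, None] * a.sum(axis=1, keepdims=True)
            pred = s * t1 + (1 - s) * pi[:, None, :] * t1.sum(axis=2, keepdims=True)
        a = pred * em
        norm = a.sum(axis=(1, 2), keepdims=True)
        bad = norm[:, 0, 0] <= 0
        if np.any(bad):
            a[bad] = 0.25
            norm[bad] = 1.0
        a = a / norm
        alphas[j] = a

    st = np.empty((n, L), dtype=np.int8)

    def _sample(wflat, uu):
        tot = wflat.sum(axis=1)
        cum = np.cumsum(wflat, axis=1)
        return np.minimum((cum < (uu * tot)[:, None]).sum(axis=1), 3).astype(np.int8)

    st[:, L - 1] = _sample(alphas[L - 1].reshape(n, 4), u[:, L - 1, 0])
    rows = np.arange(n)
    for j in range(L - 2, -1, -1):
        if is_start[j + 1]:
            w = alphas[j].reshape(n, 4)
        else:
            s = stay[j + 1]
            c1n = st[:, j + 1] >> 1
            c2n = st[:, j + 1] & 1
            pn1 = pi[rows, c1n]
            pn2 = pi[rows, c2n]
            sidx = np.arange(4)
            t1 = (1 - s) * pn1[:, None] + s * ((sidx[None, :] >> 1) == c1n[:, None])
            t2 = (1 - s) * pn2[:, None] + s * ((sidx[None, :] & 1) == c2n[:, None])
            w = alphas[j].reshape(n, 4) * t1 * t2
        st[:, j] = _sample(w, u[:, j, 0])

    c1 = (st >> 1).astype(np.int64)
    c2 = (st & 1).astype(np.int64)
    starts = np.asarray(is_start, bool)

    # stationary-draw bookkeeping for the theta and lambda updates
    nA = np.zeros(n, dtype=np.int64)
    nd = np.zeros(n, dtype=np.int64)
    for k, ck in ((1, c1), (2, c2)):
        nd += starts.sum()
        nA += (ck[:, starts] == 0).sum(axis=1)
        prev = ck[:, :-1]
        cur = ck[:, 1:]
        sj = stay[1:][None, :]
        picur = np.where(cur == 0, pi[:, [0]], pi[:, [1]])
        num = (1 - sj) * picur
        den = num + sj * (cur == prev)
        redraw = (u[:, 1:, k] * den < num) & (~starts[1:])[None, :]
        nd += redraw.sum(axis=1)
        nA += (redraw & (cur == 0)).sum(axis=1)
        Rk = np.zeros(L, dtype=np.int64)
        Rk[1:] = redraw.sum(axis=0)
        R += Rk
    nA_draw += nA
    n_draw += nd

    # per-copy allele assignment for the allele-frequency updates
    obs = geno >= 0
    p1 = np.where(c1 == 0, pA[None, :], pE[None, :])
    p2 = np.where(c2 == 0, pA[None, :], pE[None, :])
    w1 = p1 * (1 - p2)
    w2 = (1 - p1) * p2
    degenerate = (w1 + w2) <= 0
    w1 = np.where(degenerate, 0.5, w1)
    w2 = np.where(degenerate, 0.5, w2)
    het_first = u[:, :, 3] * (w1 + w2) < w1
    a1 = np.where(geno == 2, 1, np.where(geno == 1, het_first.astype(int), 0))
    a2 = np.where(geno == 2, 1, np.where(geno == 1, 1 - het_first.astype(int), 0))
    for ck, ak in ((c1, a1), (c2, a2)):
        onA = obs & (ck == 0)
        onE = obs & (ck == 1)
        totA += onA.sum(axis=0)
        varA += np.where(onA, ak, 0).sum(axis=0)
        totE += onE.sum(axis=0)
        varE += np.where(onE, ak, 0).sum(axis=0)

    if accumulate:
        # Rao-Blackwellized accumulation of exact smoothing marginals
        b = np.full((n, 2, 2), 0.25)
        for j in range(L - 1, -1, -1):
            post = alphas[j] * b
            post /= post.sum(axis=(1, 2), keepdims=True)
            gamma_acc[:, j, 0] += post[:, 0, 0]
            gamma_acc[:, j, 1] += post[:, 0, 1] + post[:, 1, 0]
            gamma_acc[:, j, 2] += post[:, 1, 1]
            if j > 0:
                em = _emission_table(geno[:, j], pA[j], pE[j]).reshape(n, 2, 2)
                bbm = em * b
                if is_start[j]:
                    const = (pi[:, :, None] * pi[:, None, :] * bbm).sum(axis=(1, 2))
                    b = np.ones((n, 2, 2)) * const[:, None, None]
                else:
                    s = stay[j]
                    t1 = s * bbm + (1 - s) * (pi[:, :, None] * bbm).sum(axis=1, keepdims=True)
                    b = s * t1 + (1 - s) * (pi[:, None, :] * t1).sum(axis=2, keepdims=True)
                b = b / b.sum(axis=(1, 2), keepdims=True)


sweep = _sweep_jit if _HAVE_NUMBA else _sweep_numpy
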