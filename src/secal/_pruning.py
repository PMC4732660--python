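"""Numba kernels for the HKY pruning likelihood.

Branch lengths arrive in expected substitutions/site; the transition matrix
uses the same closed form as :func:`secal.seqsim.hky_transition_matrix` (the
Python version is the reference, this one is the hot path).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _hky_pmat(t, kappa, freqs, out):
    a = freqs[0]
    c = freqs[1]
    g = freqs[2]
    u = freqs[3]
    r = a + g
    y = c + u
    beta = 1.0 / (2.0 * kappa * (a * g + c * u) + 2.0 * r * y)
    bt = beta * t
    e2 = np.exp(-bt)
    eR = np.exp(-bt * (r * kappa + y))
    eY = np.exp(-bt * (y * kappa + r))
    for i in range(4):
        ipur = (i == 0) or (i == 2)
        if ipur:
            pg = r
            eg = eR
            other = y
        else:
            pg = y
            eg = eY
            other = r
        for j in range(4):
            pj = freqs[j]
            jpur = (j == 0) or (j == 2)
            if j == i:
                out[i, j] = pj + pj * (other / pg) * e2 + ((pg - pj) / pg) * eg
            elif jpur == ipur:
                out[i, j] = pj + pj * (other / pg) * e2 - (pj / pg) * eg
            else:
                out[i, j] = pj * (1.0 - e2)


@njit(cache=True)
def full_pruning_fill(postorder, children, blens, tip_states, n_tips, kappa, freqs, L, C):
    """Fill per-node normalized partials ``L`` (n_nodes, n_pat, 4) and
    cumulative log-scalers ``C`` (n_nodes, n_pat) for the whole tree."""
    n_pat = tip_states.shape[1]
    pm = np.empty((4, 4))
    for oi in range(postorder.shape[0]):
        v = postorder[oi]
        for p in range(n_pat):
            C[v, p] = 0.0
            for s in range(4):
                L[v, p, s] = 1.0
        for ci in range(2):
            ch = children[v, ci]
            _hky_pmat(blens[ch], kappa, freqs, pm)
            if ch < n_tips:
                for p in range(n_pat):
                    st = tip_states[ch, p]
                    for s in range(4):
                        L[v, p, s] *= pm[s, st]
            else:
                for p in range(n_pat):
                    C[v, p] += C[ch, p]
                    for s in range(4):
                        acc = 0.0
                        for s2 in range(4):
                            acc += pm[s, s2] * L[ch, p, s2]
                        L[v, p, s] *= acc
        for p in range(n_pat):
            mx = L[v, p, 0]
            for s in range(1, 4):
                if L[v, p, s] > mx:
                    mx = L[v, p, s]
            if mx > 0.0:
                inv = 1.0 / mx
                for s in range(4):
                    L[v, p, s] *= inv
                C[v, p] += np.log(mx)


@njit(cache=True)
def path_update_fill(path, children, blens, tip_states, n_tips, kappa, freqs, L, C, Lb, Cb):
    """Recompute partials along an ancestor ``path`` (ending at the root)
    into buffers ``Lb``/``Cb``; untouched nodes are read from ``L``/``C``."""
    n_pat = tip_states.shape[1]
    pm = np.empty((4, 4))
    for i in range(path.shape[0]):
        v = path[i]
        for p in range(n_pat):
            Cb[i, p] = 0.0
            for s in range(4):
                Lb[i, p, s] = 1.0
        for ci in range(2):
            ch = children[v, ci]
            _hky_pmat(blens[ch], kappa, freqs, pm)
            in_buf = i > 0 and ch == path[i - 1]
            if ch < n_tips:
                for p in range(n_pat):
                    st = tip_states[ch, p]
                    for s in range(4):
                        Lb[i, p, s] *= pm[s, st]
            elif in_buf:
                for p in range(n_pat):
                    Cb[i, p] += Cb[i - 1, p]
                    for s in range(4):
                        acc = 0.0
                        for s2 in range(4):
                            acc += pm[s, s2] * Lb[i - 1, p, s2]
                        Lb[i, p, s] *= acc
            else:
                for p in range(n_pat):
                    Cb[i, p] += C[ch, p]
                    for s in range(4):
                        acc = 0.0
                        for s2 in range(4):
                            acc += pm[s, s2] * L[ch, p, s2]
                        Lb[i, p, s] *= acc
        for p in range(n_pat):
            mx = Lb[i, p, 0]
            for s in range(1, 4):
                if Lb[i, p, s] > mx:
                    mx = Lb[i, p, s]
            if mx > 0.0:
                inv = 1.0 / mx
                for s in range(4):
                    Lb[i, p, s] *= inv
                Cb[i, p] += np.log(mx)


@njit(cache=True)
def root_loglik(Lroot, Croot, freqs, counts):
    """Total log-likelihood from the root's partials and scalers."""
    n_pat = counts.shape[0]
    total = 0.0
    for p in range(n_pat):
        site = 0.0
        for s in range(4):
            site += freqs[s] * Lroot[p, s]
        if site <= 0.0:
            return -np.inf
        total += counts[p] * (np.log(site) + Croot[p])
    return total


@njit(cache=True)
def hky_pruning(postorder, children, blens, tip_states, counts, kappa, freqs, n_tips, L, logscale):
    """Felsenstein pruning over compressed site patterns.

    ``L`` is an (n_nodes, n_patterns, 4) workspace, ``logscale`` an
    (n_patterns,) workspace; both are overwritten.  Returns the total
    log-likelihood.
    """
    n_pat = tip_states.shape[1]
    pm = np.empty((4, 4))
    for p in range(n_pat):
        logscale[p] = 0.0
    for oi in range(postorder.shape[0]):
        v = postorder[oi]
        for p in range(n_pat):
            for s in range(4):
                L[v, p, s] = 1.0
        for ci in range(2):
            ch = children[v, ci]
            _hky_pmat(blens[ch], kappa, freqs, pm)
            if ch < n_tips:
                for p in range(n_pat):
                    st = tip_states[ch, p]
                    for s in range(4):
                        L[v, p, s] *= pm[s, st]
            else:
                for p in range(n_pat):
                    for s in range(4):
                        acc = 0.0
                        for s2 in range(4):
                            acc += pm[s, s2] * L[ch, p, s2]
                        L[v, p, s] *= acc
        for p in range(n_pat):
            mx = L[v, p, 0]
            for s in range(1, 4):
                if L[v, p, s] > mx:
                    mx = L[v, p, s]
            if 0.0 < mx < 1e-100:
                inv = 1.0 / mx
                for s in range(4):
                    L[v, p, s] *= inv
                logscale[p] += np.log(mx)
    root = postorder[postorder.shape[0] - 1]
    total = 0.0
    for p in range(n_pat):
        site = 0.0
        for s in range(4):
            site += freqs[s] * L[root, p, s]
        if site <= 0.0:
            return -np.inf
        total += counts[p] * (np.log(site) + logscale[p])
    return total
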