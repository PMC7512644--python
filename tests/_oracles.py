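"""Independent brute-force oracles: direct double-loop transcriptions of the
defining equations, kept deliberately naive (O(n^2) loops, no shared code
with the package internals beyond numpy array handling)."""

import numpy as np


def brute_count_pairs(vectors, r):
    """Unordered non-self pairs with max-norm distance <= r, by double loop."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = len(vectors)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(vectors[i] - vectors[j])) <= r:
                count += 1
    return count


def brute_univariate_dvs(x, m, tau, n=None):
    """Delay vectors [x_i, ..., x_{i+(m-1)tau}] for i = 0 .. n - 1."""
    x = np.asarray(x, dtype=float)
    if n is None:
        n = len(x) - m * tau
    return np.array([[x[i + tau * j] for j in range(m)] for i in range(n)])


def brute_sample_entropy(x, m, tau, r):
    """(count_m, count_m1, SE) with matched index populations.

    Both dimensions are evaluated over the same i = 0 .. N - m*tau - 1
    templates, so the (m+1)-dimension counts can never exceed the
    m-dimension counts.
    """
    n = len(x) - m * tau
    c_m = brute_count_pairs(brute_univariate_dvs(x, m, tau, n), r)
    c_m1 = brute_count_pairs(brute_univariate_dvs(x, m + 1, tau, n), r)
    if c_m == 0 or c_m1 == 0:
        return c_m, c_m1, float("nan")
    return c_m, c_m1, -np.log(c_m1 / c_m)


def brute_mv_dvs(data, M, tau, extend=()):
    """Concatenated multivariate DVs over i = 0 .. N - max(m_k tau_k) - 1.

    ``extend`` lists channel indices embedded at dimension m_k + 1.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0] - max(m * t for m, t in zip(M, tau))
    vecs = []
    for i in range(n):
        v = []
        for k in range(data.shape[1]):
            mk = M[k] + (1 if k in extend else 0)
            for j in range(mk):
                v.append(data[i + tau[k] * j, k])
        vecs.append(v)
    return np.array(vecs)


def brute_mv_counts(data, M, tau, r, scheme):
    """(unextended pair count, extended count or per-subspace counts)."""
    p = data.shape[1]
    c_un = brute_count_pairs(brute_mv_dvs(data, M, tau), r)
    if scheme == "naive":
        return c_un, [brute_count_pairs(brute_mv_dvs(data, M, tau, (k,)), r) for k in range(p)]
    if scheme == "full":
        pooled = np.vstack([brute_mv_dvs(data, M, tau, (k,)) for k in range(p)])
        return c_un, brute_count_pairs(pooled, r)
    if scheme == "proposed":
        return c_un, brute_count_pairs(brute_mv_dvs(data, M, tau, tuple(range(p))), r)
    raise ValueError(scheme)


def brute_mv_sample_entropy(data, M, tau, r, scheme):
    """Multivariate SE from the brute-force counts."""
    n_un = len(brute_mv_dvs(data, M, tau))
    pairs_un = n_un * (n_un - 1) / 2
    c_un, c_ext = brute_mv_counts(data, M, tau, r, scheme)
    phi_un = c_un / pairs_un
    if scheme == "naive":
        phi_ext = np.mean([c / pairs_un for c in c_ext])
    elif scheme == "full":
        n_pool = data.shape[1] * n_un
        phi_ext = c_ext / (n_pool * (n_pool - 1) / 2)
    else:
        phi_ext = c_ext / pairs_un
    if phi_un == 0 or phi_ext == 0:
        return float("nan")
    return -np.log(phi_ext / phi_un)


def brute_bhattacharyya(mu_w, sigma_w, mu_s, sigma_s):
    """Independent transcription of the Gaussian Bhattacharyya distance."""
    a = (sigma_w / sigma_s) ** 2 + (sigma_s / sigma_w) ** 2 + 2.0
    return 0.25 * np.log(0.25 * a) + 0.25 * (mu_s - mu_w) ** 2 / (sigma_s**2 + sigma_w**2)
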