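"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the library's solvers: semivariances
are evaluated through the public model function, but systems are assembled
entry by entry and solved with plain numpy.
"""

import numpy as np

from timberkrige.variogram import model_gamma


def dense_kriging_oracle(data_pts, data_vals, model, targets):
    """Full-matrix ordinary-kriging solve for small n, one target at a time."""
    data_pts = np.asarray(data_pts, float)
    data_vals = np.asarray(data_vals, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    n = len(data_pts)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                h = np.hypot(*(data_pts[i] - data_pts[j]))
                A[i, j] = model_gamma(model, h)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    preds, ses = [], []
    for t in targets:
        b = np.zeros(n + 1)
        for i in range(n):
            b[i] = model_gamma(model, np.hypot(*(data_pts[i] - t)))
        b[n] = 1.0
        sol = np.linalg.solve(A, b)
        lam, mu = sol[:n], sol[n]
        preds.append(lam @ data_vals)
        ses.append(np.sqrt(max(lam @ b[:n] + mu, 0.0)))
    return np.array(preds), np.array(ses)
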