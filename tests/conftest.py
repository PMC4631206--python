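import numpy as np
import pytest

import cytocode as cc

PLANTED = {"p-P38", "p-CREB", "p-ERK", "CK20"}


def make_planted_cohort(seed: int, n_events: int = 5000):
    """Gated, transformed, enterocyte-restricted cohort with the planted
    4-marker code; returns (X, y, feature names)."""
    em = cc.generate_cohort(n_events=n_events, dying_fraction=0.10,
                            doublet_fraction=0.05, debris_fraction=0.05,
                            seed=seed)
    emt = cc.arcsinh_transform(em)
    gate = cc.gate_dna_singlets(emt)
    cells = emt.subset(gate.mask)
    ent = cells.subset((cells.truth["population"] == "enterocyte").to_numpy())
    y = ent.truth["dying"].to_numpy().astype(int)
    feat = [c for c in ent.analyte_names if c != "CC3"]
    X = np.column_stack([ent.column(f) for f in feat])
    return X, y, feat, ent


@pytest.fixture(scope="session")
def planted_cohort():
    return make_planted_cohort(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    em = cc.generate_cohort(n_events=800, dying_fraction=0.10,
                            doublet_fraction=0.0, debris_fraction=0.0, seed=7)
    return cc.arcsinh_transform(em)


def krylov_pls_beta(X, y, n_components, scale=True):
    """Independent closed-form PLS1 oracle.

    The PLS1 weight space after A components is the Krylov space
    span{s, Cs, ..., C^{A-1}s} with s = X'y and C = X'X (on the
    centered/scaled data); the coefficient vector is the C-orthogonal
    projection of the least-squares problem onto that space:
    beta = K (K' C K)^{-1} K' s for any basis K of the Krylov space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    s = Xc.T @ yc
    C = Xc.T @ Xc
    cols, v = [], s.copy()
    for _ in range(n_components):
        cols.append(v)
        v = C @ v
    K = np.column_stack(cols)
    Q, _ = np.linalg.qr(K)
    return Q @ np.linalg.solve(Q.T @ C @ Q, Q.T @ s)


def pairwise_auc(scores, labels) -> float:
    """Concordant-pair counting AUC oracle (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    hi = np.unique(labels)[1]
    pos = scores[labels == hi]
    neg = scores[labels != hi]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def brute_kde(coords: np.ndarray) -> np.ndarray:
    """Brute-force pairwise Gaussian-kernel density with the Silverman
    bandwidth matrix H = f^2 * Cov(X), f = (n (d+2)/4)^(-1/(d+4))."""
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    f = (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
    H = np.cov(coords.T, ddof=1) * f ** 2
    Hinv = np.linalg.inv(H)
    norm = n * (2 * np.pi) ** (d / 2.0) * np.sqrt(np.linalg.det(H))
    dens = np.empty(n)
    for i in range(n):
        diff = coords - coords[i]
        dens[i] = np.exp(-0.5 * np.einsum("ij,jk,ik->i", diff, Hinv, diff)).sum()
    return dens / norm
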