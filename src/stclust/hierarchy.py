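"""Hierarchical subunit estimation by greedy splitting.

Fits to retinal data show a characteristic partitioning: increasing the
number of subunits by one typically splits a single existing subunit in
two while the rest barely change.  This module makes that structure
explicit: starting from the single-subunit (STA) fit, each level splits
one parent subunit into two children initialized as noisy copies with
the parent's weight divided equally, and refines the children with a
factorized soft assignment

    alpha_child1 = alpha_parent * sigma,   alpha_child2 = alpha_parent * (1 - sigma)

where sigma is the two-way softmax between the children (the bias b_n
is log w_n throughout).  The parent to split is chosen greedily for the
maximum gain in (approximate) log-likelihood, yielding the whole
solution path over N efficiently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import FitTrace, _fit_bank, _spike_frames, update_weights
from .model import SubunitBank, expected_nll

__all__ = [
    "HierarchyPath",
    "split_init",
    "child_assignments",
    "fit_path",
    "match_subunits",
]


@dataclass
class HierarchyPath:
    """Solution path of banks with one more subunit per level."""

    levels: list[SubunitBank] = field(default_factory=list)  # index 0 -> N=1
    split_parents: list[int] = field(default_factory=list)   # parent split at each step
    gains: list[float] = field(default_factory=list)         # surrogate-nll decrease

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def bank_at(self, n_subunits: int) -> SubunitBank:
        return self.levels[n_subunits - 1]


def split_init(bank: SubunitBank, m: int, noise_sd: float | None = None,
               seed=None) -> SubunitBank:
    """Replace subunit m by two noisy children sharing its weight equally.

    Children are ``K_m + eps_i`` with i.i.d. Gaussian noise of scale
    ``noise_sd`` (default 0.05 * |K_m| / sqrt(D)); each child weight is
    w_m / 2 exactly, i.e. e^{b_child} = e^{b_parent} / 2.  The children
    are appended in place of the parent; other subunits are untouched.
    """
    rng = np.random.default_rng(seed)
    K, w = bank.K, bank.w
    if not 0 <= m < bank.n_subunits:
        raise IndexError("parent index out of range")
    if noise_sd is None:
        noise_sd = 0.05 * np.linalg.norm(K[m]) / np.sqrt(K.shape[1])
    children_K = K[m] + noise_sd * rng.standard_normal((2, K.shape[1]))
    new_K = np.concatenate([np.delete(K, m, axis=0), children_K])
    new_w = np.concatenate([np.delete(w, m), [w[m] / 2.0, w[m] / 2.0]])
    return SubunitBank(new_K, new_w)


def child_assignments(X_spike, alpha_parent: np.ndarray,
                      K_children: np.ndarray, w_children: np.ndarray
                      ) -> np.ndarray:
    """Factorized responsibilities of two children of one parent.

    sigma_t = softmax between the children (logits K_i . X_t + log w_i);
    the parent's responsibility mass is conserved exactly:
    alpha_child1 + alpha_child2 = alpha_parent.
    """
    from .model import _frames
    frames = _frames(X_spike)
    if K_children.shape[0] != 2 or w_children.shape[0] != 2:
        raise ValueError("exactly two children expected")
    with np.errstate(divide="ignore"):
        logits = frames @ (K_children[0] - K_children[1]) + (
            np.log(w_children[0]) - np.log(w_children[1]))
    sigma = 1.0 / (1.0 + np.exp(-logits))
    first = alpha_parent * sigma
    # second child takes the exact remainder so parent mass is conserved
    return np.column_stack([first, alpha_parent - first])


def _refine_children(Xs, ys, n_bins, alpha_parent, K_children, w_children,
                     max_iter=300, tol=1e-8):
    """Iterate the factorized updates for one child pair (others frozen).

    The child pair starts as two nearly identical noisy copies of the
    parent, so symmetry breaking amplifies slowly at first; the
    iteration budget and tolerance are deliberately generous, otherwise
    splits can terminate before the children separate and collapse back
    onto the parent.
    """
    K, w = K_children.copy(), w_children.copy()
    prev = None
    for _ in range(max_iter):
        ac = child_assignments(Xs, alpha_parent, K, w)
        resp = ys[:, None] * ac
        mass = resp.sum(axis=0)
        if np.any(mass <= 1e-300):
            break  # one child starved; keep current parameters
        K = (resp.T @ Xs) / mass[:, None]
        w = update_weights(ys, ac, K, n_bins)
        # child contribution to the approximate nll (frozen terms omitted)
        obj = float(SubunitBank(K, w).strengths.sum()
                    - (resp * (Xs @ K.T + np.log(w))).sum() / n_bins)
        if prev is not None and abs(prev - obj) < tol * max(abs(prev), 1e-12):
            break
        prev = obj
    return K, w


def fit_path(X, Y, n_max: int, reg: str = "none", lam: float = 0.0,
             eps: float = 0.01, grid_shape=None, seed=None,
             noise_sd: float | None = None, refine: str = "frozen",
             max_iter: int = 100, tol: float = 1e-6) -> HierarchyPath:
    """Greedy hierarchical solution path from N=1 to N=n_max.

    At each level every current subunit is tentatively split (children
    refined to convergence with the factorized assignments, all other
    subunits frozen) and the split with the largest decrease of the
    approximate negative log-likelihood is kept.  With
    ``refine="joint"`` the whole bank is additionally refined by the
    flat algorithm after each accepted split.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    bank, _ = _flat_fit(X, Y, 1, reg, lam, eps, grid_shape,
                        int(rng.integers(2**31)), max_iter, tol)
    path = HierarchyPath(levels=[bank])
    Xs, ys, n_bins = _spike_frames(X, Y)
    cur_nll = expected_nll(bank, Xs, ys, n_bins)
    for _ in range(n_max - 1):
        from .clustering import update_activations
        alpha = update_activations(Xs, bank).alpha
        best = None
        for m in range(bank.n_subunits):
            cand = split_init(bank, m, noise_sd=noise_sd,
                              seed=int(rng.integers(2**31)))
            Kc = cand.K[-2:].copy()
            wc = cand.w[-2:].copy()
            Kc, wc = _refine_children(Xs, ys, n_bins, alpha[:, m], Kc, wc)
            new_bank = SubunitBank(np.concatenate([np.delete(bank.K, m, 0), Kc]),
                                   np.concatenate([np.delete(bank.w, m), wc]))
            val = expected_nll(new_bank, Xs, ys, n_bins)
            if best is None or val < best[0]:
                best = (val, m, new_bank)
        val, m, new_bank = best
        if refine == "joint":
            new_bank, _ = _flat_fit(X, Y, new_bank.n_subunits, reg, lam, eps,
                                    grid_shape, int(rng.integers(2**31)),
                                    max_iter, tol, init_bank=new_bank)
            val = expected_nll(new_bank, Xs, ys, n_bins)
        path.levels.append(new_bank)
        path.split_parents.append(m)
        path.gains.append(cur_nll - val)
        cur_nll = val
        bank = new_bank
    return path


def _flat_fit(X, Y, n, reg, lam, eps, grid_shape, seed, max_iter, tol,
              init_bank=None):
    K, W, trace = _fit_bank(X, [Y], n, lam=lam, reg=reg, eps=eps,
                            grid_shape=grid_shape, seed=seed,
                            max_iter=max_iter, tol=tol, init_bank=init_bank)
    return SubunitBank(K, W[0]), trace


def match_subunits(bankA: SubunitBank, bankB: SubunitBank):
    """Greedy pairing of subunits across two banks by filter alignment.

    Repeatedly pairs the remaining filters with the largest normalized
    inner product.  When bank B has one extra subunit, the unmatched B
    subunits are the presumed split products.

    Returns
    -------
    pairs : list of (index_in_A, index_in_B, cosine)
    unmatched_b : list of B indices left unpaired
    """
    if abs(bankA.n_subunits - bankB.n_subunits) > 1:
        raise ValueError("banks differ by more than one subunit")
    A = bankA.K / np.linalg.norm(bankA.K, axis=1, keepdims=True)
    B = bankB.K / np.linalg.norm(bankB.K, axis=1, keepdims=True)
    sim = A @ B.T
    pairs = []
    free_a = set(range(A.shape[0]))
    free_b = set(range(B.shape[0]))
    while free_a and free_b:
        i, j = max(((i, j) for i in free_a for j in free_b),
                   key=lambda ij: sim[ij])
        pairs.append((i, j, float(sim[i, j])))
        free_a.remove(i)
        free_b.remove(j)
    return pairs, sorted(free_b)
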