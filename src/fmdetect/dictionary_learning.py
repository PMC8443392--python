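"""K-SVD learning of FM / non-FM feature dictionaries and the OMP sparse coder.

Two complete dictionaries (256 x 256 at the defaults) are learned from
window training sets: D1 from fetal-movement windows and D2 from non-FM
windows (breathing, background vibration, sensor noise). Learning solves

    min_{D,X} ||Y - D X||_F^2   s.t.  ||x_i||_0 <= T0  for every column i,

by alternating (a) sparse coding of all training columns with orthogonal
matching pursuit and (b) atom-by-atom updates: for atom j, the residual
matrix restricted to the columns that use j (with atom j's own contribution
added back) is decomposed by SVD, and the atom and its coefficient row are
replaced by the leading singular pair. Each atom update is the optimal
rank-1 refit of its subproblem, so the objective is non-increasing across a
dictionary-update sweep with the supports held fixed.

Training and test windows are mean-removed and scaled to unit l2 norm before
coding ("shape only"): amplitude information is already consumed by the
upstream amplitude gate, so the dictionaries capture waveform morphology.
Because every training column is mean-free, the learned atoms are mean-free
as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateInputError, ParameterError

#: Atom count of a complete dictionary at the default window length.
DEFAULT_N_ATOMS = 256

#: Default OMP sparsity (maximum nonzero coefficients per code).
DEFAULT_T0 = 3

#: Default number of K-SVD alternations.
DEFAULT_N_ITER = 30

#: Early-stop threshold on the relative objective improvement per iteration.
KSVD_REL_TOL = 1e-6

#: Residual considered numerically zero inside OMP.
OMP_RESIDUAL_TOL = 1e-12


@dataclass
class TrainingSet:
    """Matrix of training windows (one per column) with a class label."""

    Y: np.ndarray  # shape (m, L)
    class_label: str  # "FM" or "NON_FM"
    components: list[str] | None = None  # optional per-column provenance tags
    peaks: np.ndarray | None = None  # optional pre-normalization peak amplitudes (g)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("training set must be a 2-D matrix (m x L)")

    @property
    def m(self) -> int:
        return self.Y.shape[0]

    @property
    def L(self) -> int:
        return self.Y.shape[1]


@dataclass
class FeatureDictionary:
    """A learned dictionary of unit-norm atoms with a class label."""

    D: np.ndarray  # shape (m, n), unit-norm columns
    class_label: str
    metadata: dict = field(default_factory=dict)
    #: per-iteration (objective after coding, objective after update) pairs
    history: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("dictionary must be a 2-D matrix (m x n)")

    @property
    def m(self) -> int:
        return self.D.shape[0]

    @property
    def n(self) -> int:
        return self.D.shape[1]

    @property
    def atom_norms(self) -> np.ndarray:
        return np.linalg.norm(self.D, axis=0)


@dataclass
class SparseCode:
    """An OMP code: full coefficient vector plus its support set."""

    coefficients: np.ndarray  # length n; exactly zero off the support
    support: list[int]
    sparsity_limit: int


def normalize_signal(y: np.ndarray) -> np.ndarray:
    """Mean-remove and scale to unit l2 norm (the coding convention)."""
    y = np.asarray(y, dtype=float)
    centered = y - y.mean()
    norm = float(np.linalg.norm(centered))
    if norm < 1e-12:
        raise DegenerateInputError("signal has (numerically) zero norm after centering")
    return centered / norm


# ---------------------------------------------------------------------------
# Orthogonal matching pursuit
# ---------------------------------------------------------------------------

def _omp_column(D: np.ndarray, y: np.ndarray, T0: int):
    """Greedy OMP for one signal; returns (coefficients, support, residual)."""
    r = y.copy()
    support: list[int] = []
    coef_s = np.empty(0)
    for _ in range(T0):
        if np.linalg.norm(r) <= OMP_RESIDUAL_TOL:
            break
        c = D.T @ r
        if support:
            c[support] = 0.0
        j = int(np.argmax(np.abs(c)))
        if abs(c[j]) <= OMP_RESIDUAL_TOL:
            break
        support.append(j)
        coef_s, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
        r = y - D[:, support] @ coef_s
    coefficients = np.zeros(D.shape[1])
    if support:
        coefficients[support] = coef_s
    return coefficients, support, r


def omp_code(D: FeatureDictionary | np.ndarray, y: np.ndarray, T0: int = DEFAULT_T0) -> SparseCode:
    """Sparse-code ``y`` against the dictionary with at most T0 atoms.

    At each step the atom with maximal absolute correlation to the current
    residual is selected and all coefficients on the accumulated support are
    re-fit by least squares, which leaves the residual orthogonal to the span
    of the selected atoms.
    """
    Dm = D.D if isinstance(D, FeatureDictionary) else np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    if T0 < 1:
        raise ParameterError(f"T0 must be >= 1, got {T0}")
    if T0 > Dm.shape[1]:
        raise ParameterError(f"T0={T0} exceeds the atom count n={Dm.shape[1]}")
    if y.shape != (Dm.shape[0],):
        raise ParameterError(
            f"signal length {y.shape} does not match atom length {Dm.shape[0]}"
        )
    if float(np.linalg.norm(y)) < 1e-12:
        raise DegenerateInputError("cannot code a zero-norm signal")
    coefficients, support, _ = _omp_column(Dm, y, T0)
    return SparseCode(coefficients=coefficients, support=support, sparsity_limit=T0)


def omp_code_matrix(D: np.ndarray, Y: np.ndarray, T0: int) -> np.ndarray:
    """Code every column of Y; returns the coefficient matrix X (n x L)."""
    n, L = D.shape[1], Y.shape[1]
    X = np.zeros((n, L))
    for i in range(L):
        coefficients, support, _ = _omp_column(D, Y[:, i], T0)
        X[:, i] = coefficients
    return X


def residual_norms(D: np.ndarray, Y: np.ndarray, T0: int) -> np.ndarray:
    """Residual l2 norm of the T0-sparse OMP code of each column of Y."""
    out = np.empty(Y.shape[1])
    for i in range(Y.shape[1]):
        _, _, r = _omp_column(D, Y[:, i], T0)
        out[i] = np.linalg.norm(r)
    return out


def reconstruction_error(D: FeatureDictionary | np.ndarray, code: SparseCode,
                         y: np.ndarray) -> float:
    """Euclidean norm of the reconstruction residual ||y - D x||_2."""
    Dm = D.D if isinstance(D, FeatureDictionary) else np.asarray(D, dtype=float)
    return float(np.linalg.norm(np.asarray(y, dtype=float) - Dm @ code.coefficients))


# ---------------------------------------------------------------------------
# K-SVD
# ---------------------------------------------------------------------------

def _fix_sign(u: np.ndarray, v: np.ndarray):
    """Deterministic sign convention: largest-|.| element of the atom positive."""
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        return -u, -v
    return u, v


def ksvd_train(ts: TrainingSet, n_atoms: int = DEFAULT_N_ATOMS, T0: int = DEFAULT_T0,
               n_iter: int = DEFAULT_N_ITER, seed: int = 0) -> FeatureDictionary:
    """Learn a unit-norm dictionary from the training set by K-SVD.

    The dictionary is initialized from ``n_atoms`` randomly chosen training
    columns (normalized). Each iteration sparse-codes every column with OMP
    and then refits every atom via the leading singular pair of its
    restricted residual matrix. Atoms that no column selects are replaced by
    the currently worst-represented training column. Training stops early
    when the relative objective improvement drops below ``KSVD_REL_TOL``.
    """
    Y = ts.Y
    if not np.all(np.isfinite(Y)):
        raise DataError("training matrix contains non-finite values")
    m, L = Y.shape
    if L < n_atoms:
        raise ParameterError(
            f"complete-dictionary training needs L >= n_atoms, got L={L}, "
            f"n_atoms={n_atoms}"
        )
    if T0 > n_atoms:
        raise ParameterError(f"T0={T0} exceeds n_atoms={n_atoms}")
    rng = np.random.default_rng(seed)

    col_norms = np.linalg.norm(Y, axis=0)
    usable = np.flatnonzero(col_norms > 1e-12)
    if usable.size < n_atoms:
        raise DataError("not enough nonzero training columns to initialize atoms")
    init_cols = rng.choice(usable, size=n_atoms, replace=False)
    D = Y[:, init_cols] / col_norms[init_cols]

    history: list[tuple[float, float]] = []
    prev_obj = np.inf
    for _ in range(n_iter):
        X = omp_code_matrix(D, Y, T0)
        obj_coding = float(np.linalg.norm(Y - D @ X))

        for j in range(n_atoms):
            users = np.flatnonzero(X[j, :] != 0.0)
            if users.size == 0:
                # dead atom: replace with the worst-represented column
                res = np.linalg.norm(Y - D @ X, axis=0)
                worst = int(np.argmax(res))
                if res[worst] <= 1e-12:
                    continue
                D[:, j] = Y[:, worst] / np.linalg.norm(Y[:, worst])
                X[j, :] = 0.0
                continue
            E = Y[:, users] - D @ X[:, users] + np.outer(D[:, j], X[j, users])
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            u, v = _fix_sign(U[:, 0], Vt[0, :])
            D[:, j] = u
            X[j, users] = s[0] * v

        obj_update = float(np.linalg.norm(Y - D @ X))
        history.append((obj_coding, obj_update))
        if np.isfinite(prev_obj) and prev_obj > 0:
            if (prev_obj - obj_update) / prev_obj < KSVD_REL_TOL:
                prev_obj = obj_update
                break
        prev_obj = obj_update

    return FeatureDictionary(
        D=D,
        class_label=ts.class_label,
        metadata={
            "m": m,
            "n": n_atoms,
            "T0": T0,
            "n_iter": n_iter,
            "seed": seed,
            "L": L,
        },
        history=history,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_dictionary(fd: FeatureDictionary, path) -> None:
    """Save a dictionary plus metadata; round-trips losslessly (binary floats)."""
    meta = dict(fd.metadata)
    meta["class_label"] = fd.class_label
    np.savez(
        path,
        D=fd.D,
        metadata=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        history=np.asarray(fd.history, dtype=float).reshape(-1, 2),
    )


def load_dictionary(path) -> FeatureDictionary:
    """Load a dictionary container written by :func:`save_dictionary`."""
    with np.load(path) as z:
        D = z["D"]
        meta = json.loads(bytes(z["metadata"].tobytes()).decode("utf-8"))
        history = [tuple(row) for row in z["history"]]
    class_label = meta.pop("class_label", "FM")
    return FeatureDictionary(D=D, class_label=class_label, metadata=meta, history=history)
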