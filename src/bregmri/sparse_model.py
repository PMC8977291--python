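"""Patch-based sparse modeling.

Patches R_i u are extracted as columns of X; an overcomplete dictionary D
(unit-norm atoms) codes them either greedily (OMP) or through an l1
split-Bregman coder with an optional graph-Laplacian coupling term
Tr(Gamma L Gamma^T) that pulls codes of similar patches together.

The coder's split objective is

    sum_i ||a_i||_1 + (lam/2)||z_i||^2 + mu_g * Tr(Gamma L Gamma^T)
        + (beta/2)||z_i + D a_i - x_i - y_i/beta||^2

with auxiliary residuals z_i and multipliers y_i; eliminating z at
convergence leaves  ||Gamma||_1 + (lam/2)||X - D Gamma||_F^2 + graph term,
i.e. a Laplacian-coupled LASSO over all patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import orthogonal_mp
from sklearn.neighbors import NearestNeighbors


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Vectorized patches: columns of ``patches`` (n x M_p, n = p^2) are the
    raster-ordered p x p patches of the source image."""

    patches: np.ndarray
    patch_size: int
    stride: int
    periodic: bool
    source_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.patches.shape[1]

    @property
    def patch_dim(self) -> int:
        return self.patches.shape[0]


@dataclass
class Dictionary:
    """Atom matrix D (n x J); every column is kept at unit l2 norm."""

    atoms: np.ndarray

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(norms > 1.0 + 1e-9):
            raise ValueError("dictionary atoms must satisfy ||d_q||_2 <= 1")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def patch_dim(self) -> int:
        return self.atoms.shape[0]


@dataclass
class CodeMatrix:
    """Sparse codes Gamma (J x M_p), one column per patch."""

    codes: np.ndarray
    sparsity_target: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape


@dataclass
class SimilarityGraph:
    """Mutual-kNN patch similarity graph with Gaussian weights and its
    combinatorial Laplacian L = Diag(W 1) - W."""

    weights: sp.spmatrix
    laplacian: sp.spmatrix

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class SplitVariables:
    """Auxiliary residuals z_i, multipliers y_i and the penalty beta of the
    split coder (column layout matching the patch matrix).  The coder also
    records its per-sweep merit objective here."""

    z: np.ndarray
    y: np.ndarray
    beta: float
    objective_history: list[float] | None = None


# --------------------------------------------------------------------------
# patch extraction / reassembly
# --------------------------------------------------------------------------

def extract_patches(image: np.ndarray, patch_size: int = 8, stride: int = 1,
                    periodic: bool = True) -> PatchSet:
    """Extract vectorized p x p patches in raster order.

    With ``periodic=True`` patches wrap around the image borders; at stride 1
    this yields exactly M*N patches and sum_i R_i^T R_i = p^2 * I.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    M, N = image.shape
    p = int(patch_size)
    if p <= 0 or stride <= 0:
        raise ValueError("patch_size and stride must be positive")
    if p > min(M, N):
        raise ValueError(f"patch_size {p} exceeds image extent {image.shape}")
    if stride > p:
        warnings.warn("stride exceeds patch_size: pixels will be skipped",
                      stacklevel=2)

    if periodic:
        padded = np.pad(image, ((0, p - 1), (0, p - 1)), mode="wrap")
        windows = sliding_window_view(padded, (p, p))[::stride, ::stride]
    else:
        windows = sliding_window_view(image, (p, p))[::stride, ::stride]
    gr, gc = windows.shape[:2]
    patches = windows.reshape(gr * gc, p * p).T.copy()
    return PatchSet(patches=patches, patch_size=p, stride=stride,
                    periodic=periodic, source_shape=(M, N))


def reassemble_patches(patchset: PatchSet, values: np.ndarray | None = None
                       ) -> np.ndarray:
    """Average overlapping patch copies back into an image.

    Each pixel equals the mean of every patch copy covering it; this is
    (sum_i R_i^T v_i) divided elementwise by the overlap count.  Passing
    ``values=None`` reassembles the stored patches (identity round trip).
    """
    if values is None:
        values = patchset.patches
    values = np.asarray(values, dtype=float)
    if values.shape != patchset.patches.shape:
        raise ValueError(
            f"values shape {values.shape} does not match patch set "
            f"{patchset.patches.shape}"
        )
    acc, cnt = _accumulate(patchset, values)
    if np.any(cnt == 0):
        raise ValueError("patch geometry leaves uncovered pixels")
    return acc / cnt


def overlap_counts(patchset: PatchSet) -> np.ndarray:
    """Per-pixel number of patch copies (p^2 everywhere for periodic
    stride-1 geometry)."""
    _, cnt = _accumulate(patchset, patchset.patches)
    return cnt


def _accumulate(patchset: PatchSet, values: np.ndarray):
    M, N = patchset.source_shape
    p, stride = patchset.patch_size, patchset.stride
    if patchset.periodic:
        gr = len(range(0, M, stride))
        gc = len(range(0, N, stride))
        ext_r, ext_c = M + p - 1, N + p - 1
    else:
        gr = len(range(0, M - p + 1, stride))
        gc = len(range(0, N - p + 1, stride))
        ext_r, ext_c = M, N
    cube = values.T.reshape(gr, gc, p, p)
    acc = np.zeros((ext_r, ext_c))
    cnt = np.zeros((ext_r, ext_c))
    rows = stride * np.arange(gr)
    cols = stride * np.arange(gc)
    for di in range(p):
        for dj in range(p):
            acc[np.ix_(rows + di, cols + dj)] += cube[:, :, di, dj]
            cnt[np.ix_(rows + di, cols + dj)] += 1.0
    if patchset.periodic:  # fold the wrapped margin back
        for arr in (acc, cnt):
            arr[: p - 1, :N] += arr[M:, :N]
            arr[:M, : p - 1] += arr[:M, N:]
            arr[: p - 1, : p - 1] += arr[M:, N:]
        acc = acc[:M, :N]
        cnt = cnt[:M, :N]
    return acc, cnt


# --------------------------------------------------------------------------
# dictionary
# --------------------------------------------------------------------------

def init_dictionary(patch_dim: int, n_atoms: int, method: str = "dct",
                    seed: int = 0) -> Dictionary:
    """Initial dictionary: overcomplete 2D-DCT (default) or seeded random
    unit-norm atoms.  The first DCT atom is the constant (DC) atom."""
    if patch_dim <= 0 or n_atoms <= 0:
        raise ValueError("patch_dim and n_atoms must be positive")
    if n_atoms < patch_dim:
        warnings.warn("undercomplete dictionary (n_atoms < patch_dim)",
                      stacklevel=2)
    if method == "dct":
        p = int(round(np.sqrt(patch_dim)))
        if p * p != patch_dim:
            raise ValueError("dct initialization needs a square patch_dim")
        m = int(np.ceil(np.sqrt(n_atoms)))
        base = np.zeros((p, m))
        for k in range(m):
            v = np.cos(np.pi * k * (np.arange(p) + 0.5) / m)
            if k > 0:
                v = v - v.mean()
            base[:, k] = v / np.linalg.norm(v)
        atoms = np.kron(base, base)[:, :n_atoms]
    elif method == "random":
        rng = np.random.default_rng(seed)
        atoms = rng.standard_normal((patch_dim, n_atoms))
    else:
        raise ValueError(f"unknown init method {method!r}")
    atoms = atoms / np.linalg.norm(atoms, axis=0, keepdims=True)
    return Dictionary(atoms=atoms)


def update_dictionary(dictionary: Dictionary, patchset: PatchSet,
                      codes: CodeMatrix, xi: float = 1.0,
                      max_backtracks: int = 30) -> Dictionary:
    """Residual-gradient dictionary update with column renormalization.

    Performs D <- normalize(D + xi' * (X - D Gamma) Gamma^T) where xi' starts
    at ``xi`` (scaled by the gradient magnitude) and is halved until the fit
    residual ||X - D Gamma||_F does not increase.  Atoms that collapse to
    zero norm are re-seeded from the worst-fit patch.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    D = dictionary.atoms
    X = patchset.patches
    G = codes.codes
    if G.shape != (D.shape[1], X.shape[1]):
        raise ValueError("code matrix shape does not match dictionary/patches")

    R = X - D @ G
    base_resid = np.linalg.norm(R)
    grad = R @ G.T
    gnorm = np.linalg.norm(grad)
    if gnorm == 0.0:
        return Dictionary(atoms=D.copy())
    step = xi / max(np.linalg.norm(G @ G.T, 2), 1e-12)  # ~1/Lipschitz scale

    worst = int(np.argmax(np.linalg.norm(R, axis=0)))
    for _ in range(max_backtracks):
        Dn = D + step * grad
        norms = np.linalg.norm(Dn, axis=0)
        dead = norms < 1e-12
        if np.any(dead):
            Dn[:, dead] = X[:, worst:worst + 1]
            norms = np.linalg.norm(Dn, axis=0)
            dead = norms < 1e-12
            Dn[:, dead] = 1.0  # constant fallback for an all-zero patch
            norms = np.linalg.norm(Dn, axis=0)
        Dn = Dn / norms
        if np.linalg.norm(X - Dn @ G) <= base_resid * (1 + 1e-12):
            return Dictionary(atoms=Dn)
        step *= 0.5
    return Dictionary(atoms=D.copy())  # step underflow: keep current atoms


# --------------------------------------------------------------------------
# sparse coding
# --------------------------------------------------------------------------

def sparse_code_omp(patchset: PatchSet, dictionary: Dictionary,
                    sparsity_T: int = 6, tol: float | None = None
                    ) -> CodeMatrix:
    """Greedy per-patch OMP coding with at most ``sparsity_T`` atoms per
    column (or residual tolerance ``tol``)."""
    X = patchset.patches
    if not np.all(np.isfinite(X)):
        raise ValueError("patch matrix contains non-finite values")
    if tol is None and sparsity_T < 1:
        raise ValueError("need sparsity_T >= 1 or a positive tol")
    D = dictionary.atoms
    codes = np.zeros((D.shape[1], X.shape[1]))
    nz = np.linalg.norm(X, axis=0) > 0
    if np.any(nz):
        sol = orthogonal_mp(
            D, X[:, nz],
            n_nonzero_coefs=None if tol is not None else int(sparsity_T),
            tol=tol, precompute=True,
        )
        codes[:, nz] = sol.reshape(D.shape[1], -1)
    return CodeMatrix(codes=codes, sparsity_target=None if tol else int(sparsity_T))


def build_similarity_graph(patchset: PatchSet, k_neighbors: int = 8,
                           kernel_sigma: float | None = None
                           ) -> SimilarityGraph:
    """Mutual-kNN graph over patches with Gaussian edge weights
    W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)).

    ``kernel_sigma`` defaults to the median neighbor distance.  The
    Laplacian L = Diag(W 1) - W is symmetric PSD with zero row sums.
    """
    X = patchset.patches.T  # nodes as rows
    m = X.shape[0]
    if k_neighbors >= m:
        raise ValueError("k_neighbors must be smaller than the number of patches")
    if kernel_sigma is not None and kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # remove self matches by index (duplicates may displace the self hit)
    keep_d = np.empty((m, k_neighbors))
    keep_i = np.empty((m, k_neighbors), dtype=int)
    for i in range(m):
        not_self = idx[i] != i
        if not_self.sum() > k_neighbors:
            not_self[np.flatnonzero(not_self)[k_neighbors:]] = False
        keep_d[i] = dist[i][not_self][:k_neighbors]
        keep_i[i] = idx[i][not_self][:k_neighbors]
    dist, idx = keep_d, keep_i

    if kernel_sigma is None:
        med = float(np.median(dist))
        kernel_sigma = med if med > 0 else 1.0

    rows = np.repeat(np.arange(m), k_neighbors)
    cols = idx.ravel()
    adj = sp.csr_matrix((np.ones(m * k_neighbors), (rows, cols)), shape=(m, m))
    mutual = adj.minimum(adj.T)  # keep i-j only if both directions present
    w = sp.csr_matrix(
        (np.exp(-dist.ravel() ** 2 / (2 * kernel_sigma ** 2)), (rows, cols)),
        shape=(m, m),
    )
    W = w.multiply(mutual)
    W = W.maximum(W.T)
    W.setdiag(0.0)
    W.eliminate_zeros()
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    return SimilarityGraph(weights=W.tocsr(), laplacian=L.tocsr())


def laplacian_energy(codes: CodeMatrix | np.ndarray,
                     graph: SimilarityGraph) -> float:
    """Tr(Gamma L Gamma^T) = 1/2 sum_ij W_ij ||a_i - a_j||^2."""
    G = codes.codes if isinstance(codes, CodeMatrix) else np.asarray(codes)
    if G.shape[1] != graph.n_nodes:
        raise ValueError(
            f"code matrix has {G.shape[1]} columns but graph has "
            f"{graph.n_nodes} nodes"
        )
    return float(np.sum(G * (G @ graph.laplacian)))


def _coder_objective(X, D, G, lam, mu_graph, graph) -> float:
    """Merit function: ||Gamma||_1 + (lam/2)||X - D Gamma||_F^2 + graph term."""
    val = np.abs(G).sum() + 0.5 * lam * np.linalg.norm(X - D @ G) ** 2
    if graph is not None and mu_graph > 0:
        val += mu_graph * laplacian_energy(G, graph)
    return float(val)


def sparse_code_bregman(
    patchset: PatchSet,
    dictionary: Dictionary,
    graph: SimilarityGraph | None = None,
    lam: float = 0.1,
    mu_graph: float = 0.01,
    beta: float = 1.0,
    n_inner: int = 10,
    n_ista: int = 5,
) -> tuple[CodeMatrix, SplitVariables]:
    """l1 split-Bregman coder with optional graph-Laplacian coupling.

    Alternates, for ``n_inner`` sweeps:

    * z-update (closed form):  z = beta (X + Y/beta - D Gamma) / (lam + beta)
    * Gamma-update: ``n_ista`` proximal-gradient (soft-threshold) steps on
      (beta/2)||D Gamma - C||^2 + mu_graph Tr(Gamma L Gamma^T) + ||Gamma||_1
      with C = X + Y/beta - z
    * multiplier update:  Y <- Y - beta (z + D Gamma - X)

    The merit objective (the eliminated-z form) is tracked per sweep; three
    consecutive increases raise with the offending parameters named.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if lam <= 0:
        raise ValueError("lam must be positive")
    X = patchset.patches
    if not np.all(np.isfinite(X)):
        raise ValueError("patch matrix contains non-finite values")
    D = dictionary.atoms
    J, m = D.shape[1], X.shape[1]
    if graph is not None and graph.n_nodes != m:
        raise ValueError("graph size does not match the number of patches")
    use_graph = graph is not None and mu_graph > 0

    G = np.zeros((J, m))
    Z = np.zeros_like(X)
    Y = np.zeros_like(X)

    lip = beta * np.linalg.norm(D, 2) ** 2
    if use_graph:
        lip += 2.0 * mu_graph * 2.0 * float(graph.laplacian.diagonal().max())
    step = 1.0 / lip

    prev_obj = np.inf
    n_up = 0
    history: list[float] = []
    for sweep in range(n_inner):
        Z = beta * (X + Y / beta - D @ G) / (lam + beta)
        C = X + Y / beta - Z
        for _ in range(n_ista):
            grad = beta * (D.T @ (D @ G - C))
            if use_graph:
                grad += 2.0 * mu_graph * (G @ graph.laplacian)
            G = G - step * grad
            G = np.sign(G) * np.maximum(np.abs(G) - step, 0.0)
        Y = Y - beta * (Z + D @ G - X)

        obj = _coder_objective(X, D, G, lam, mu_graph, graph if use_graph else None)
        history.append(obj)
        # divergence: three consecutive rises that also exceed the starting
        # value (transient multiplier-driven rises below it are benign)
        if obj > prev_obj * (1 + 1e-6):
            n_up += 1
            if n_up >= 3 and obj > history[0]:
                raise RuntimeError(
                    "split coder diverging (objective rose 3 consecutive "
                    f"sweeps) at sweep {sweep}: lam={lam}, mu_graph={mu_graph}, "
                    f"beta={beta}, n_ista={n_ista}"
                )
        else:
            n_up = 0
        prev_obj = min(prev_obj, obj)

    return (CodeMatrix(codes=G, sparsity_target=None),
            SplitVariables(z=Z, y=Y, beta=beta, objective_history=history))
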