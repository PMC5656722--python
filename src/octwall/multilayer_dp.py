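"""Simultaneous extraction of three non-crossing wall contours.

The intima-media (IM), media-adventitia (MA) and adventitia-periadventitia
(AP) interfaces of the arterial wall are extracted *at once* by a dynamic
program running in a 4D space ``(x, y1, y2, y3)``: ``x`` walks along the
circumference of the vessel (columns of the replicated polar sub-image) and
``y_n`` is the depth of the n-th interface.  A cumulative cost is front
propagated column by column,

    C(x, y1, y2, y3) = min_{dy1, dy2, dy3}  C(x-1, y1+dy1, y2+dy2, y3+dy3)
        + sum_n  w_n (1 + kappa |dy_n|) (Cn(x, y_n) + Cn(x-1, y_n+dy_n))

where ``Cn`` is the positive cost map ``C+`` for the IM and AP interfaces
(dark-to-bright edges are penalised, bright-to-dark favoured) and ``C-`` for
the MA interface.  Admissible states obey the minimum-gap constraint
``y1 + g <= y2`` and ``y2 + g <= y3`` so the contours can never cross, and
each interface may move by at most ``N`` pixels per column.  Backtracking
from the cheapest final state yields the globally optimal multi-parametric
path; the central third of the triple-replicated image is kept, which closes
the contours in the Cartesian plane.

Although the joint state space is 3D per column, the transition cost is
separable per interface, so each front-propagation step is computed exactly
with three sequential 1D relaxations (min-convolutions) instead of a
(2N+1)^3 enumeration.  For full-resolution clinical geometries the state
space is additionally reduced by an optional depth-downsampling pass whose
result is refined by a second, band-restricted run of the same joint DP at
full resolution (see :func:`segment_layers`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cost_maps import CostMaps, compute_cost_maps

__all__ = [
    "DPParams",
    "CumulativeCost",
    "LayerContours",
    "propagate_front",
    "backtrack",
    "truncate_central",
    "segment_layers",
    "brute_force_oracle",
    "single_contour_dp",
]


@dataclass(frozen=True)
class DPParams:
    """Parameters of the front-propagation scheme.

    Defaults are the method's reference operating point: interface weights
    ``omega = (0.2, 1, 1)`` (the IM interface is down-weighted because it
    lies in an ambiguous strongly-negative-gradient region, like the AP),
    smoothness ``kappa = 0.1``, ``2N+1 = 7`` reachable neighbours, and a
    minimal inter-contour gap of 45 um.
    """

    omega: tuple[float, float, float] = (0.2, 1.0, 1.0)
    kappa: float = 0.1
    N: int = 3
    gap_um: float = 45.0
    gap_px: int | None = None  # resolved against a pixel size when needed

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.omega):
            raise ValueError("interface weights must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.gap_px is not None and self.gap_px < 1:
            raise ValueError("gap_px must be >= 1")

    def resolve_gap(self, pixel_size_axial: float) -> "DPParams":
        """Return a copy with ``gap_px = max(1, round(gap_um / pixel))``."""
        if self.gap_px is not None:
            return self
        g = max(1, round(self.gap_um / pixel_size_axial))
        return replace(self, gap_px=g)


@dataclass
class CumulativeCost:
    """Fully propagated cumulative cost.

    ``values[x]`` is the cost cube over states ``(y1, y2, y3)`` at column
    ``x`` (inadmissible states are ``+inf``).  Storing the cubes themselves
    keeps the forward pass to pure running minima; the arg-min displacement
    of any state is re-derived during backtracking, where ties are broken
    exactly by the smallest ``(dy1, dy2, dy3)``.
    """

    values: list[np.ndarray]
    costs: CostMaps
    depth: int
    n_cols: int
    params: DPParams
    gap_px: int = 1
    admissible: np.ndarray = field(repr=False, default=None)

    @property
    def final_values(self) -> np.ndarray:
        return self.values[-1]


@dataclass
class LayerContours:
    """Per-column depths (sub-image pixels) of the IM, MA, AP interfaces."""

    y1: np.ndarray
    y2: np.ndarray
    y3: np.ndarray
    n_angles: int
    pixel_size_axial: float
    gap_px: int = 1
    N: int = 3

    def as_array(self) -> np.ndarray:
        return np.stack([self.y1, self.y2, self.y3])

    def validate(self) -> None:
        y1, y2, y3 = self.y1, self.y2, self.y3
        if not (len(y1) == len(y2) == len(y3) == self.n_angles):
            raise ValueError("contour length mismatch")
        if np.any(y1 + self.gap_px > y2) or np.any(y2 + self.gap_px > y3):
            raise ValueError("gap constraint violated")
        for y in (y1, y2, y3):
            step = np.abs(np.diff(np.concatenate([y, y[:1]])))
            if np.any(step > self.N):
                raise ValueError("per-step displacement bound violated")

    def thickness_um(self) -> dict[str, np.ndarray]:
        ps = self.pixel_size_axial
        return {
            "intima": self.y1 * ps,
            "media": (self.y2 - self.y1) * ps,
            "adventitia": (self.y3 - self.y2) * ps,
        }


def _admissible_mask(depth: int, gap: int) -> np.ndarray:
    y = np.arange(depth)
    m12 = y[:, None] + gap <= y[None, :]
    return m12[:, :, None] & m12[None, :, :]


def _relax_axis0(A: np.ndarray, cur: np.ndarray, prev: np.ndarray,
                 w: float, kappa: float, N: int) -> np.ndarray:
    """Exact min over dy for the interface indexed along axis 0 of ``A``.

    ``A[yp, ...]`` holds cumulative costs at the predecessor depth ``yp``;
    ``cur``/``prev`` are that interface's cost-map columns at ``x``/``x-1``.
    Returns the relaxed cube indexed by the new depth ``y``.
    """
    d = A.shape[0]
    out = np.full(A.shape, np.inf, dtype=A.dtype)
    tail = (1,) * (A.ndim - 1)
    for dy in range(-N, N + 1):
        lo, hi = max(0, -dy), d - max(0, dy)
        if lo >= hi:
            continue
        trans = w * (1.0 + kappa * abs(dy)) * (cur[lo:hi] + prev[lo + dy:hi + dy])
        np.minimum(out[lo:hi], A[lo + dy:hi + dy] + trans.reshape((-1,) + tail),
                   out=out[lo:hi])
    return out


def propagate_front(costs: CostMaps, params: DPParams,
                    gap_px: int | None = None) -> CumulativeCost:
    """Build the 4D cumulative cost over the replicated width.

    The cost at the first column is zero for every admissible state.
    Propagation is purely left-to-right: closure of the contours comes only
    from the triple replication of the gradient image.
    """
    if gap_px is None:
        gap_px = params.gap_px
    if gap_px is None:
        raise ValueError("gap_px unresolved; call params.resolve_gap first")
    cp, cm = costs.C_plus, costs.C_minus
    depth, n_cols = cp.shape
    if n_cols < 3:
        raise ValueError("replicated width must be >= 3")
    if depth < 2 * gap_px + 1:
        raise ValueError("depth too small for gap constraint")
    adm = _admissible_mask(depth, gap_px)
    w1, w2, w3 = params.omega
    kappa, N = params.kappa, params.N

    values = [np.where(adm, 0.0, np.inf)]
    for x in range(1, n_cols):
        # three sequential exact relaxations, one per interface
        b = _relax_axis0(values[-1], cp[:, x], cp[:, x - 1], w1, kappa, N)
        b = np.moveaxis(_relax_axis0(np.moveaxis(b, 1, 0), cm[:, x],
                                     cm[:, x - 1], w2, kappa, N), 0, 1)
        b = np.moveaxis(_relax_axis0(np.moveaxis(b, 2, 0), cp[:, x],
                                     cp[:, x - 1], w3, kappa, N), 0, 2)
        values.append(np.where(adm, b, np.inf))
    return CumulativeCost(values=values, costs=costs, depth=depth,
                          n_cols=n_cols, params=params, gap_px=gap_px,
                          admissible=adm)


def backtrack(cum: CumulativeCost) -> tuple[np.ndarray, float]:
    """Follow stored predecessors from the cheapest admissible final state.

    Ties at the final column are broken by the lexicographically smallest
    ``(y1, y2, y3)``; predecessor ties were broken stage-wise toward the
    smallest displacement during propagation.  Returns ``(path, cost)``
    where ``path`` has shape ``(3, n_cols)``.
    """
    vals = cum.final_values
    flat = int(np.argmin(vals))  # first occurrence == lexicographic smallest
    total = float(vals.flat[flat])
    if not np.isfinite(total):
        raise RuntimeError("no admissible path")
    state = np.array(np.unravel_index(flat, vals.shape), dtype=np.int64)
    N = cum.params.N
    cp, cm = cum.costs.C_plus, cum.costs.C_minus
    maps = (cp, cm, cp)
    w, kappa = cum.params.omega, cum.params.kappa
    d = cum.depth
    r = np.arange(-N, N + 1)
    D = np.stack(np.meshgrid(r, r, r, indexing="ij"),
                 axis=-1).reshape(-1, 3)  # lexicographic (dy1, dy2, dy3)
    path = np.empty((3, cum.n_cols), dtype=np.int64)
    path[:, -1] = state
    for x in range(cum.n_cols - 1, 0, -1):
        pred = state[None, :] + D
        ok = np.all((pred >= 0) & (pred < d), axis=1)
        predc = np.clip(pred, 0, d - 1)
        # same summation order as the forward pass: ((A + t1) + t2) + t3
        cand = cum.values[x - 1][predc[:, 0], predc[:, 1], predc[:, 2]]
        for n in range(3):
            cand = cand + (w[n] * (1.0 + kappa * np.abs(D[:, n]).astype(float))
                           * (maps[n][state[n], x] + maps[n][predc[:, n], x - 1]))
        cand[~ok] = np.inf
        state = pred[int(np.argmin(cand))]
        path[:, x - 1] = state
    return path, total


def path_cost(path: np.ndarray, costs: CostMaps, params: DPParams) -> float:
    """Forward recomputation of a path's total cumulative cost."""
    cp, cm = costs.C_plus, costs.C_minus
    maps = (cp, cm, cp)
    total = 0.0
    for x in range(1, path.shape[1]):
        for n in range(3):
            y, yp = path[n, x], path[n, x - 1]
            dy = yp - y
            total += params.omega[n] * (1 + params.kappa * abs(dy)) * (
                maps[n][y, x] + maps[n][yp, x - 1])
    return float(total)


def truncate_central(path: np.ndarray, W: int, pixel_size_axial: float = 1.0,
                     params: DPParams | None = None,
                     gap_px: int = 1) -> LayerContours:
    """Keep the central replica of a path over the 3W replicated columns."""
    if path.shape[1] != 3 * W:
        raise ValueError(f"path length {path.shape[1]} != 3*W = {3 * W}")
    N = params.N if params is not None else 3
    if params is not None and params.gap_px is not None:
        gap_px = params.gap_px
    central = path[:, W:2 * W]
    wrap = np.abs(central[:, 0] - central[:, -1])
    if np.any(wrap > N):
        warnings.warn("closure violated: circular wrap step exceeds N",
                      RuntimeWarning, stacklevel=2)
    return LayerContours(y1=central[0].copy(), y2=central[1].copy(),
                         y3=central[2].copy(), n_angles=W,
                         pixel_size_axial=pixel_size_axial,
                         gap_px=gap_px, N=N)


# ---------------------------------------------------------------------------
# coarse-to-fine machinery for full-resolution frames
# ---------------------------------------------------------------------------

def _downsample_costs(c: np.ndarray, f: int) -> np.ndarray:
    d = c.shape[0]
    pad = (-d) % f
    if pad:
        c = np.concatenate([c, np.repeat(c[-1:], pad, axis=0)], axis=0)
    return c.reshape(-1, f, c.shape[1]).mean(axis=1)


def _circular_smooth(y: np.ndarray, width: int = 5) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(y.astype(float), size=width, mode="wrap")


def _banded_refine(cp: np.ndarray, cm: np.ndarray, base: np.ndarray,
                   params: DPParams, gap_px: int, band: int) -> np.ndarray:
    """Joint DP restricted to ``+-band`` around per-interface base contours.

    Same transition model and constraints as :func:`propagate_front`, but
    the per-column depth range of interface ``n`` is ``base[n, x] + z``
    with ``z`` in ``[-band, band]``.  Exact within the band; preserves the
    gap and per-step constraints by construction.
    """
    depth, n_cols = cp.shape
    K = 2 * band + 1
    w = params.omega
    kappa, N = params.kappa, params.N
    maps = (cp, cm, cp)
    base = np.clip(np.round(base).astype(int), band, depth - 1 - band)
    z = np.arange(-band, band + 1)

    def adm_at(x: int) -> np.ndarray:
        yy = [base[n, x] + z for n in range(3)]
        m12 = yy[0][:, None] + gap_px <= yy[1][None, :]
        m23 = yy[1][:, None] + gap_px <= yy[2][None, :]
        return m12[:, :, None] & m23[None, :, :]

    def relax(A: np.ndarray, n: int, x: int) -> np.ndarray:
        # axis 0 of A indexes the predecessor offset z' of interface n
        db = base[n, x - 1] - base[n, x]
        cur = maps[n][base[n, x] + z, x]
        prev = maps[n][base[n, x - 1] + z, x - 1]
        out = np.full(A.shape, np.inf, dtype=A.dtype)
        tail = (1,) * (A.ndim - 1)
        for dy in range(-N, N + 1):
            # y' = y + dy  ->  z' = z + dy - db
            sft = dy - db
            lo, hi = max(0, -sft), K - max(0, sft)
            if lo >= hi:
                continue
            trans = (w[n] * (1.0 + kappa * abs(dy))
                     * (cur[lo:hi] + prev[lo + sft:hi + sft]))
            np.minimum(out[lo:hi],
                       A[lo + sft:hi + sft] + trans.reshape((-1,) + tail),
                       out=out[lo:hi])
        return out

    values = [np.where(adm_at(0), 0.0, np.inf)]
    for x in range(1, n_cols):
        b = relax(values[-1], 0, x)
        b = np.moveaxis(relax(np.moveaxis(b, 1, 0), 1, x), 0, 1)
        b = np.moveaxis(relax(np.moveaxis(b, 2, 0), 2, x), 0, 2)
        values.append(np.where(adm_at(x), b, np.inf))

    flat = int(np.argmin(values[-1]))
    if not np.isfinite(values[-1].flat[flat]):
        raise RuntimeError("banded refinement infeasible")
    zstate = np.array(np.unravel_index(flat, values[-1].shape), dtype=np.int64)
    r = np.arange(-N, N + 1)
    D = np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)
    path = np.empty((3, n_cols), dtype=np.int64)
    path[:, -1] = base[:, -1] + z[zstate]
    for x in range(n_cols - 1, 0, -1):
        db = base[:, x - 1] - base[:, x]
        zpred = zstate[None, :] + D - db[None, :]
        ok = np.all((zpred >= 0) & (zpred < K), axis=1)
        zpredc = np.clip(zpred, 0, K - 1)
        cand = values[x - 1][zpredc[:, 0], zpredc[:, 1], zpredc[:, 2]]
        for n in range(3):
            y = base[n, x] + z[zstate[n]]
            yp = base[n, x - 1] + z[zpredc[:, n]]
            cand = cand + (w[n] * (1.0 + kappa * np.abs(D[:, n]).astype(float))
                           * (maps[n][y, x] + maps[n][yp, x - 1]))
        cand[~ok] = np.inf
        zstate = zpred[int(np.argmin(cand))]
        path[:, x - 1] = base[:, x - 1] + z[zstate]
    return path


def segment_layers(sub, params: DPParams | None = None, sigma_um: float = 30.0,
                   downsample: int | str = "auto") -> LayerContours:
    """Full segmentation of one polar sub-image.

    Composition: gradient image -> triple replication -> cost pair ->
    front propagation -> backtracking -> central truncation.  When the
    depth exceeds ~40 px the dense state cube is impractical, so the DP
    first runs on depth-downsampled cost maps (block-mean by factor ``f``)
    and the result is refined by a band-restricted joint DP at full
    resolution, which keeps the global structure while restoring per-pixel
    accuracy.
    """
    if params is None:
        params = DPParams()
    params = params.resolve_gap(sub.pixel_size_axial)
    gap_px = params.gap_px
    costs = compute_cost_maps(sub, sigma_um=sigma_um)
    depth, n_rep = costs.C_plus.shape
    W = sub.n_angles

    if downsample == "auto":
        f = max(1, int(np.ceil(depth / 32)))
    else:
        f = max(1, int(downsample))

    if f == 1:
        cum = propagate_front(costs, params, gap_px=gap_px)
        path, _ = backtrack(cum)
        return truncate_central(path, W, sub.pixel_size_axial, params=params)

    cp_c = _downsample_costs(costs.C_plus, f)
    cm_c = _downsample_costs(costs.C_minus, f)
    gap_c = max(1, int(np.ceil(gap_px / f)))
    coarse_costs = CostMaps(I_G=costs.I_G, I_G_rep=costs.I_G_rep,
                            C_plus=cp_c, C_minus=cm_c,
                            sigma_um=costs.sigma_um, sigma_px=costs.sigma_px)
    cum = propagate_front(coarse_costs, params, gap_px=gap_c)
    coarse_path, _ = backtrack(cum)

    base = coarse_path.astype(float) * f + f / 2.0
    base = np.stack([_circular_smooth(b) for b in base])
    band = max(2 * f, params.N + 1)
    for attempt in range(3):
        try:
            path = _banded_refine(costs.C_plus, costs.C_minus, base, params,
                                  gap_px, band)
            break
        except RuntimeError:
            band *= 2
    else:  # pragma: no cover - smooth phantoms never get here
        raise RuntimeError("refinement infeasible at maximal band width")
    return truncate_central(path, W, sub.pixel_size_axial, params=params)


# ---------------------------------------------------------------------------
# independent oracle and single-contour reduction
# ---------------------------------------------------------------------------

def brute_force_oracle(costs: CostMaps, params: DPParams,
                       gap_px: int | None = None,
                       max_extensions: int = 10_000_000
                       ) -> tuple[np.ndarray, float]:
    """Exhaustive enumeration of all admissible non-crossing triple paths.

    Independent of the front-propagation code: every admissible state
    sequence with per-step ``|dy| <= N`` is enumerated explicitly and the
    cheapest total transition cost is returned together with one arg-min
    path (first in lexicographic state order).  Intended for tiny
    instances only; raises once the number of path extensions exceeds
    ``max_extensions``.
    """
    if gap_px is None:
        gap_px = params.gap_px if params.gap_px is not None else 1
    cp, cm = costs.C_plus, costs.C_minus
    depth, n_cols = cp.shape
    ys = np.arange(depth)
    states = np.array([(a, b, c) for a in ys for b in ys for c in ys
                       if a + gap_px <= b and b + gap_px <= c], dtype=np.int64)
    if len(states) == 0:
        raise ValueError("depth too small for gap constraint")
    n_states = len(states)
    dy = states[:, None, :] - states[None, :, :]  # pred - succ? see below
    # adjacency: transition from state j (column x-1) to state i (column x)
    ok = np.all(np.abs(dy) <= params.N, axis=2)

    maps = (cp, cm, cp)
    w, kappa = params.omega, params.kappa

    def trans_matrix(x: int) -> np.ndarray:
        T = np.zeros((n_states, n_states))
        for n in range(3):
            yj = states[:, n][:, None]  # predecessor depth
            yi = states[:, n][None, :]  # successor depth
            pen = w[n] * (1.0 + kappa * np.abs(yj - yi))
            T += pen * (maps[n][states[:, n], x][None, :]
                        + maps[n][states[:, n], x - 1][:, None])
        T[~ok] = np.inf
        return T

    # vectorised breadth expansion over columns
    ends = np.arange(n_states)          # current end state of each partial path
    costs_acc = np.zeros(n_states)
    seqs = ends[:, None]
    extensions = n_states
    for x in range(1, n_cols):
        T = trans_matrix(x)
        succ_lists = [np.nonzero(ok[j])[0] for j in range(n_states)]
        counts = np.array([len(succ_lists[j]) for j in ends])
        extensions += int(counts.sum())
        if extensions > max_extensions:
            raise RuntimeError("oracle bound exceeded")
        new_ends = np.concatenate([succ_lists[j] for j in ends])
        rep = np.repeat(np.arange(len(ends)), counts)
        costs_acc = costs_acc[rep] + T[ends[rep], new_ends]
        seqs = np.concatenate([seqs[rep], new_ends[:, None]], axis=1)
        ends = new_ends
    best = int(np.argmin(costs_acc))
    best_cost = float(costs_acc[best])
    path = states[seqs[best]].T  # (3, n_cols)
    return path, best_cost


def single_contour_dp(cost: np.ndarray, kappa: float = 0.1, N: int = 3,
                      weight: float = 1.0) -> tuple[np.ndarray, float]:
    """1D counterpart of the front propagation, for a single interface.

    Same transition model, run on a single cost map: used for the lumen
    contour and as the degenerate limit of the triple DP when two interface
    weights vanish.  Returns ``(path, total_cost)`` over all columns of
    ``cost`` (no replication or truncation here).
    """
    depth, n_cols = cost.shape
    values = np.zeros(depth)
    preds = np.empty((n_cols - 1, depth), dtype=np.int8)
    for x in range(1, n_cols):
        out = np.full(depth, np.inf)
        arg = np.zeros(depth, dtype=np.int8)
        for i, dy in enumerate(range(-N, N + 1)):
            lo, hi = max(0, -dy), depth - max(0, dy)
            if lo >= hi:
                continue
            trans = weight * (1.0 + kappa * abs(dy)) * (
                cost[lo:hi, x] + cost[lo + dy:hi + dy, x - 1])
            cand = values[lo + dy:hi + dy] + trans
            seg = out[lo:hi]
            better = cand < seg
            seg[better] = cand[better]
            arg[lo:hi][better] = i
        values = out
        preds[x - 1] = arg
    y = int(np.argmin(values))
    total = float(values[y])
    path = np.empty(n_cols, dtype=np.int64)
    path[-1] = y
    for x in range(n_cols - 1, 0, -1):
        y = y + int(preds[x - 1][y]) - N
        path[x - 1] = y
    return path, total
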