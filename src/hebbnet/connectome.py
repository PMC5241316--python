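"""Construction of the multi-area architecture.

The default network consists of 12 cortical areas — six perisylvian
("language") areas A1, AB, PB, PF_i, PM_i, M1_i and six extrasylvian
("semantic") areas V1, TO, AT, PF_L, PM_L, M1_L — each a 25x25 grid of
excitatory cells paired one-to-one with a 25x25 grid of graded inhibitory
cells.  Excitatory projections (within and between areas) are sparse, random
and topographic: the probability of a link between two cells falls off as a
Gaussian of their grid distance and is clipped to zero outside a square
neighbourhood (side ``n_exc`` for excitatory, ``n_inh`` for
excitatory-to-inhibitory projections).  Initial excitatory weights are i.i.d.
uniform on [0, 0.1].  Each inhibitory cell pools the excitatory activity of
its 5x5 neighbourhood with fixed weights and inhibits only its twin
excitatory cell; these local inhibitory loops are non-plastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .params import ConfigError, ConnectomeParams

__all__ = [
    "PERISYLVIAN_AREAS",
    "EXTRASYLVIAN_AREAS",
    "DEFAULT_AREAS",
    "DEFAULT_EDGES",
    "Connectome",
    "topographic_sample",
    "build_inhibitory_loops",
    "build_architecture",
]

PERISYLVIAN_AREAS = ("A1", "AB", "PB", "PF_i", "PM_i", "M1_i")
EXTRASYLVIAN_AREAS = ("V1", "TO", "AT", "PF_L", "PM_L", "M1_L")
DEFAULT_AREAS = EXTRASYLVIAN_AREAS + PERISYLVIAN_AREAS

# Undirected between-area edges; each is realized as two directed sparse
# projections.  Next-neighbour chains, hub cross-links between the four
# multimodal areas, within-modality "jumping" links and long-distance
# links between the auditory/articulatory and visual/motor systems.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    # next-neighbour chains
    ("A1", "AB"), ("AB", "PB"), ("PB", "PF_i"), ("PF_i", "PM_i"), ("PM_i", "M1_i"),
    ("V1", "TO"), ("TO", "AT"), ("AT", "PF_L"), ("PF_L", "PM_L"), ("PM_L", "M1_L"),
    # hub cross-links
    ("AT", "PB"), ("AT", "PF_i"), ("PB", "PF_L"), ("PF_i", "PF_L"),
    # jumping links
    ("A1", "PB"), ("PF_i", "M1_i"), ("PF_L", "M1_L"), ("V1", "AT"),
    # long-distance links
    ("PB", "PM_i"), ("AB", "PF_i"), ("AT", "PM_L"), ("TO", "PF_L"),
)


def topographic_sample(
    grid: int,
    n: int,
    p0: float,
    sigma: float,
    rng: np.random.Generator,
    exclude_self: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample sparse topographic links between two same-sized cell grids.

    Each source cell at grid position (r, c) links to the target cell at
    (r+dr, c+dc), for offsets within the n x n square, independently with
    probability ``p0 * exp(-(dr^2+dc^2) / (2 sigma^2))``.  Neighbourhoods are
    clipped at the grid boundary (no wrap-around); links outside the square
    never occur.

    Returns (source_index, target_index) arrays of flat cell indices.
    """
    if n % 2 == 0 or n < 1:
        raise ConfigError(f"neighbourhood side must be odd and >= 1, got {n}")
    if not 0.0 <= p0 <= 1.0:
        raise ConfigError(f"p0 must be in [0, 1], got {p0}")
    half = n // 2
    src_list: list[np.ndarray] = []
    tgt_list: list[np.ndarray] = []
    rr, cc = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    flat = rr * grid + cc
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            if exclude_self and dr == 0 and dc == 0:
                continue
            p = p0 * np.exp(-(dr * dr + dc * dc) / (2.0 * sigma * sigma))
            # valid source positions: target (r+dr, c+dc) inside the grid
            r_ok = (rr + dr >= 0) & (rr + dr < grid)
            c_ok = (cc + dc >= 0) & (cc + dc < grid)
            valid = r_ok & c_ok
            hit = (rng.random((grid, grid)) < p) & valid
            if not hit.any():
                continue
            s = flat[hit]
            t = s + dr * grid + dc
            src_list.append(s)
            tgt_list.append(t)
    if not src_list:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(src_list), np.concatenate(tgt_list)


def build_inhibitory_loops(grid: int, n_inh: int, e2i_total: float) -> sp.csr_matrix:
    """Fixed excitatory -> inhibitory pooling weights for one area.

    Inhibitory cell (r, c) receives from every excitatory cell in its
    ``n_inh`` x ``n_inh`` neighbourhood (clipped at the boundary), with each
    link weighted ``e2i_total / count`` so the pooled drive is the local mean
    firing.  The returned matrix maps excitatory outputs to inhibitory inputs
    (shape: cells x cells).  The reverse path (each inhibitory cell
    inhibiting only its twin) is a diagonal handled separately.
    """
    half = n_inh // 2
    n_cells = grid * grid
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for r in range(grid):
        for c in range(grid):
            r0, r1 = max(0, r - half), min(grid, r + half + 1)
            c0, c1 = max(0, c - half), min(grid, c + half + 1)
            count = (r1 - r0) * (c1 - c0)
            w = e2i_total / count
            for rr in range(r0, r1):
                for cc in range(c0, c1):
                    rows.append(r * grid + c)
                    cols.append(rr * grid + cc)
                    vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_cells))


@dataclass
class Connectome:
    """The realized area graph: sparse weights plus geometry metadata.

    ``W_ee`` holds every plastic excitatory-to-excitatory synapse (rows =
    postsynaptic cell, cols = presynaptic cell), covering both within-area
    recurrent maps and between-area projections.  ``W_ie`` holds the fixed
    excitatory-to-inhibitory pooling weights; ``i2e`` the fixed per-cell
    inhibitory-to-twin weights (negative).
    """

    areas: list[str]
    grid: int
    W_ee: sp.csr_matrix
    W_ie: sp.csr_matrix
    i2e: np.ndarray
    edges: list[tuple[str, str]]
    params: ConnectomeParams
    seed: int | None = None
    _post_of: np.ndarray | None = field(default=None, repr=False)

    # -- geometry -------------------------------------------------------------

    @property
    def cells_per_area(self) -> int:
        return self.grid * self.grid

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_exc(self) -> int:
        """Total number of excitatory cells."""
        return self.n_areas * self.cells_per_area

    @property
    def n_cells(self) -> int:
        """Total cells, excitatory + inhibitory."""
        return 2 * self.n_exc

    @property
    def area_index(self) -> np.ndarray:
        """Area id per excitatory cell (int array of length n_exc)."""
        return np.repeat(np.arange(self.n_areas), self.cells_per_area)

    def area_slice(self, area: str) -> slice:
        i = self.areas.index(area)
        return slice(i * self.cells_per_area, (i + 1) * self.cells_per_area)

    @property
    def post_of(self) -> np.ndarray:
        """Postsynaptic cell index for each stored synapse of W_ee (cached)."""
        if self._post_of is None or len(self._post_of) != self.W_ee.nnz:
            counts = np.diff(self.W_ee.indptr)
            self._post_of = np.repeat(np.arange(self.W_ee.shape[0]), counts)
        return self._post_of

    # -- serialization --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the connectome to a portable .npz container (lossless)."""
        edges_arr = np.array([f"{a}|{b}" for a, b in self.edges])
        np.savez_compressed(
            path,
            areas=np.array(self.areas),
            grid=np.int64(self.grid),
            seed=np.int64(-1 if self.seed is None else self.seed),
            edges=edges_arr,
            ee_data=self.W_ee.data,
            ee_indices=self.W_ee.indices,
            ee_indptr=self.W_ee.indptr,
            ie_data=self.W_ie.data,
            ie_indices=self.W_ie.indices,
            ie_indptr=self.W_ie.indptr,
            i2e=self.i2e,
            cp=np.array(
                [
                    self.params.grid, self.params.n_exc, self.params.n_inh,
                    self.params.p0, self.params.sigma_factor, self.params.w_init_max,
                    self.params.i2e_weight, self.params.e2i_total,
                ]
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Connectome":
        with np.load(path, allow_pickle=False) as f:
            areas = [str(a) for a in f["areas"]]
            grid = int(f["grid"])
            n = len(areas) * grid * grid
            W_ee = sp.csr_matrix(
                (f["ee_data"], f["ee_indices"], f["ee_indptr"]), shape=(n, n)
            )
            W_ie = sp.csr_matrix(
                (f["ie_data"], f["ie_indices"], f["ie_indptr"]), shape=(n, n)
            )
            cp = f["cp"]
            params = ConnectomeParams(
                grid=int(cp[0]), n_exc=int(cp[1]), n_inh=int(cp[2]), p0=float(cp[3]),
                sigma_factor=float(cp[4]), w_init_max=float(cp[5]),
                i2e_weight=float(cp[6]), e2i_total=float(cp[7]),
            )
            seed = int(f["seed"])
            edges = [tuple(e.split("|")) for e in f["edges"]]
            return cls(
                areas=areas, grid=grid, W_ee=W_ee, W_ie=W_ie, i2e=f["i2e"],
                edges=edges, params=params, seed=None if seed < 0 else seed,
            )


def build_architecture(
    params: ConnectomeParams | None = None,
    rng: np.random.Generator | int | None = None,
    areas: list[str] | None = None,
    edges: list[tuple[str, str]] | None = None,
) -> Connectome:
    """Build the full architecture: recurrent maps, projections, local loops.

    With the default area and edge lists this realizes the 12-area, 22-edge
    graph (every edge reciprocal, hence 44 directed projections plus 12
    within-area recurrent maps).  Alternative area/edge lists use the same
    code path, which is how the miniature test architectures are built.
    """
    params = params or ConnectomeParams()
    params.validate()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    areas = list(areas) if areas is not None else list(DEFAULT_AREAS)
    edges = [tuple(e) for e in edges] if edges is not None else list(DEFAULT_EDGES)
    for a, b in edges:
        for name in (a, b):
            if name not in areas:
                raise ConfigError(f"edge references unknown area {name!r}")
        if a == b:
            raise ConfigError(f"self-edge {a!r}-{b!r} not allowed (use recurrent maps)")

    g = params.grid
    npa = g * g
    n_total = len(areas) * npa
    sigma_e = params.sigma_factor * params.n_exc
    idx = {name: i for i, name in enumerate(areas)}

    src_all: list[np.ndarray] = []
    tgt_all: list[np.ndarray] = []
    # within-area recurrent maps (no self-synapses)
    for name in areas:
        off = idx[name] * npa
        s, t = topographic_sample(g, params.n_exc, params.p0, sigma_e, rng, exclude_self=True)
        src_all.append(s + off)
        tgt_all.append(t + off)
    # between-area projections, both directions per undirected edge
    for a, b in edges:
        for sa, ta in ((a, b), (b, a)):
            s, t = topographic_sample(g, params.n_exc, params.p0, sigma_e, rng)
            src_all.append(s + idx[sa] * npa)
            tgt_all.append(t + idx[ta] * npa)

    src = np.concatenate(src_all)
    tgt = np.concatenate(tgt_all)
    weights = rng.uniform(0.0, params.w_init_max, size=len(src))
    # rows = postsynaptic target, cols = presynaptic source
    W_ee = sp.csr_matrix((weights, (tgt, src)), shape=(n_total, n_total))
    W_ee.sum_duplicates()

    loop = build_inhibitory_loops(g, params.n_inh, params.e2i_total)
    W_ie = sp.block_diag([loop] * len(areas), format="csr")
    i2e = np.full(n_total, params.i2e_weight)

    return Connectome(
        areas=areas, grid=g, W_ee=W_ee, W_ie=W_ie, i2e=i2e,
        edges=edges, params=params,
    )
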