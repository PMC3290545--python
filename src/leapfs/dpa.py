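"""Dynamics Perturbation Analysis (DPA) over an anisotropic elastic network.

The protein is modelled as a network of Calpha nodes joined by harmonic
springs (spring constant ``gamma``) whenever two nodes lie within a
cutoff ``r_c`` (default 10.5 A).  In thermal equilibrium the network's
conformational fluctuations are Gaussian with precision matrix equal to
the 3N x 3N Hessian (k_B T is absorbed into ``gamma``; only ratios enter
the analysis).

A field of test points is placed just outside the molecular surface.
Each point ``m`` is tethered to every node within ``r_s`` (default
15.5 A) by springs of strength ``gamma_s = 12 gamma``, giving a
perturbed Hessian and hence a perturbed Gaussian ensemble.  The signal
at a point is the relative entropy ``D_x`` between the perturbed and
unperturbed ensembles, evaluated after projecting out the rigid-body
null modes of the unperturbed Hessian.  Points whose ``D_x`` falls in
the upper tail of an extreme-value (Gumbel) fit are clustered in space
(OPTICS, DBSCAN-style extraction at a single reachability), and the
residues with a heavy atom within 5 A of a cluster become a predicted
functional site.  Sites are ranked by their cluster's mean ``D_x`` and
labelled O, P, Q, ... in decreasing order; selected-but-unclustered
points are labelled XX and sub-threshold points NN.

The default relative-entropy direction is KL(perturbed || unperturbed);
the reverse is available via ``direction="0_to_m"``.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial import cKDTree
from sklearn.cluster import OPTICS

from ._aa import vdw_radius
from .structure_io import DomainStructure, ResidueKey

logger = logging.getLogger(__name__)

R_C_DEFAULT = 10.5      # node-node cutoff, Angstrom
R_S_DEFAULT = 15.5      # point-node cutoff, Angstrom
GAMMA_S_RATIO = 12.0    # point-spring strength relative to gamma
PROBE_RADIUS = 1.5      # surface probe radius, Angstrom
POINT_DENSITY = 1.0     # target surface density, points per A^2
EVD_QUANTILE = 0.96     # fitted-CDF threshold for point selection
CLUSTER_EPS = 5.0       # reachability threshold, Angstrom
CLUSTER_MIN_PTS = 3
SITE_CUTOFF = 5.0       # point-to-residue heavy atom cutoff, Angstrom

#: Cluster letters in rank order (highest mean D_x first).
SITE_LETTERS = "OPQRSTUVWYZ" + string.ascii_uppercase


class DegenerateFieldError(ValueError):
    """Raised when the D_x distribution cannot support a tail fit."""


class NumericalRankError(ValueError):
    """Raised when a Hessian is singular on the projected subspace."""


@dataclass(eq=False)
class ElasticNetwork:
    nodes: np.ndarray      # (N, 3)
    gamma: float
    r_c: float
    hessian: np.ndarray    # (3N, 3N)


@dataclass(eq=False)
class DPASite:
    site_label: str
    residues: frozenset[ResidueKey]
    mean_dx: float
    point_indices: np.ndarray


@dataclass(eq=False)
class SurfacePointField:
    points: np.ndarray          # (M, 3)
    dx: np.ndarray              # (M,)
    labels: list[str]           # per point: cluster letter, "NN", or "XX"
    sites: list[DPASite] = field(default_factory=list)


def build_enm(
    nodes: np.ndarray | DomainStructure,
    r_c: float = R_C_DEFAULT,
    gamma: float = 1.0,
) -> ElasticNetwork:
    """Assemble the anisotropic network Hessian for a set of nodes.

    For each pair within ``r_c`` the off-diagonal 3x3 block is
    ``-gamma * u u^T`` with ``u`` the unit bond vector; diagonal blocks
    make every block row sum to zero (translational invariance).
    """
    if isinstance(nodes, DomainStructure):
        nodes = nodes.ca_coords()
    nodes = np.asarray(nodes, dtype=float)
    n = len(nodes)
    if n < 2:
        raise ValueError("elastic network needs at least 2 nodes")
    hess = np.zeros((3 * n, 3 * n))
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(r_c, output_type="ndarray")
    degree = np.zeros(n, dtype=int)
    for i, j in pairs:
        d = nodes[j] - nodes[i]
        dist = np.linalg.norm(d)
        if dist == 0:
            continue
        u = d / dist
        block = gamma * np.outer(u, u)
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
        degree[i] += 1
        degree[j] += 1
    if np.any(degree == 0):
        logger.warning(
            "elastic network has %d isolated node(s); the network is disconnected",
            int(np.sum(degree == 0)),
        )
    return ElasticNetwork(nodes=nodes, gamma=gamma, r_c=r_c, hessian=hess)


def perturbed_hessian(
    enm: ElasticNetwork,
    point: np.ndarray,
    r_s: float = R_S_DEFAULT,
    gamma_s_ratio: float = GAMMA_S_RATIO,
) -> tuple[np.ndarray, int]:
    """Hessian with a fixed test point tethered to all nodes within ``r_s``.

    Each tethered node's diagonal block gains ``gamma_s u u^T`` along the
    node-to-point unit vector (the point itself is held fixed, so no new
    degrees of freedom appear).  Returns the new Hessian and the number
    of tethered nodes (0 means the input was returned unchanged).
    """
    point = np.asarray(point, dtype=float)
    gamma_s = gamma_s_ratio * enm.gamma
    hess = enm.hessian.copy()
    n_contacts = 0
    for i, node in enumerate(enm.nodes):
        d = point - node
        dist = np.linalg.norm(d)
        if dist == 0 or dist > r_s:
            continue
        u = d / dist
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] += gamma_s * np.outer(u, u)
        n_contacts += 1
    return hess, n_contacts


def _projected_forms(h0: np.ndarray, hm: np.ndarray):
    """Project both quadratic forms off the null modes of ``h0``."""
    if h0.shape != hm.shape:
        raise ValueError(f"hessian size mismatch: {h0.shape} vs {hm.shape}")
    w, v = eigh(h0)
    tol = max(w[-1], 1.0) * len(w) * np.finfo(float).eps * 100
    keep = w > tol
    d = int(np.sum(keep))
    if d == 0:
        raise NumericalRankError("unperturbed Hessian has no positive modes")
    vk = v[:, keep]
    a0 = w[keep]                   # diagonal of projected h0
    am = vk.T @ hm @ vk
    return a0, am, d


def relative_entropy(h0: np.ndarray, hm: np.ndarray, direction: str = "m_to_0") -> float:
    """Relative entropy between the Gaussian ensembles of two Hessians.

    Both ensembles are restricted to the complement of the rigid-body
    null space of ``h0`` before the closed-form Gaussian KL divergence is
    evaluated.  ``direction="m_to_0"`` (default) gives KL(perturbed ||
    unperturbed); ``"0_to_m"`` the reverse.  Either way the result is
    >= 0, and 0 iff the two forms agree on the projected subspace.
    """
    a0, am, d = _projected_forms(h0, hm)
    try:
        c, low = cho_factor(am)
    except np.linalg.LinAlgError as exc:
        raise NumericalRankError(
            "perturbed Hessian singular on the projected subspace"
        ) from exc
    logdet_am = 2.0 * np.sum(np.log(np.diag(c)))
    logdet_a0 = float(np.sum(np.log(a0)))
    am_inv = cho_solve((c, low), np.eye(d))
    if direction == "m_to_0":
        # 0.5 [ tr(A0 Am^-1) - d + ln det Am - ln det A0 ]
        dx = 0.5 * (np.sum(a0 * np.diag(am_inv)) - d + logdet_am - logdet_a0)
    elif direction == "0_to_m":
        # 0.5 [ tr(Am A0^-1) - d + ln det A0 - ln det Am ]
        dx = 0.5 * (np.sum(np.diag(am) / a0) - d + logdet_a0 - logdet_am)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return max(float(dx), 0.0)


class DPAEngine:
    """Per-point D_x evaluation sharing one eigendecomposition.

    The perturbation at a point is a sum of rank-one spring terms, so on
    the projected subspace ``Hm = A0 + W W^T`` and

        D_x = 1/2 sum_i [ ln(1 + l_i) - l_i / (1 + l_i) ]   (m_to_0)
        D_x = 1/2 sum_i [ l_i - ln(1 + l_i) ]               (0_to_m)

    over the eigenvalues ``l_i`` of ``B = W^T A0^{-1} W``.  This agrees
    with :func:`relative_entropy` on the corresponding full matrices and
    makes a whole surface field cheap to evaluate.
    """

    def __init__(
        self,
        enm: ElasticNetwork,
        r_s: float = R_S_DEFAULT,
        gamma_s_ratio: float = GAMMA_S_RATIO,
        direction: str = "m_to_0",
    ):
        if direction not in ("m_to_0", "0_to_m"):
            raise ValueError(f"unknown direction {direction!r}")
        self.enm = enm
        self.r_s = r_s
        self.gamma_s = gamma_s_ratio * enm.gamma
        self.direction = direction
        w, v = eigh(enm.hessian)
        tol = max(w[-1], 1.0) * len(w) * np.finfo(float).eps * 100
        keep = w > tol
        self._w = w[keep]
        self._v = v[:, keep]
        self._tree = cKDTree(enm.nodes)

    def dx(self, point: np.ndarray) -> float:
        point = np.asarray(point, dtype=float)
        contacts = self._tree.query_ball_point(point, r=self.r_s)
        if not contacts:
            return 0.0
        n = len(self.enm.nodes)
        u = np.zeros((3 * n, len(contacts)))
        for col, i in enumerate(contacts):
            d = point - self.enm.nodes[i]
            dist = np.linalg.norm(d)
            if dist == 0:
                continue
            u[3 * i:3 * i + 3, col] = d / dist
        w_mat = math.sqrt(self.gamma_s) * (self._v.T @ u)       # (d, k)
        b = (w_mat / self._w[:, None]).T @ w_mat                # (k, k)
        lam = np.clip(np.linalg.eigvalsh(b), 0.0, None)
        if self.direction == "m_to_0":
            val = 0.5 * np.sum(np.log1p(lam) - lam / (1.0 + lam))
        else:
            val = 0.5 * np.sum(lam - np.log1p(lam))
        return max(float(val), 0.0)

    def field(self, points: np.ndarray) -> np.ndarray:
        return np.array([self.dx(p) for p in np.asarray(points, dtype=float)])


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A rigid-motion-equivariant frame (origin, axes) for a point cloud.

    Axes are principal axes ordered by decreasing variance, each signed
    so the third moment along it is non-negative, with handedness fixed
    by the cross product.  Used so that surface-point lattices co-move
    exactly under global rotation/translation of the structure.
    """
    coords = np.asarray(coords, dtype=float)
    origin = coords.mean(axis=0)
    centered = coords - origin
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1]  # descending variance
    for k in range(3):
        skew = np.sum((centered @ axes[:, k]) ** 3)
        if skew < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return origin, axes


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit directions."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_surface_points(
    atoms_or_coords,
    elements: list[str] | None = None,
    probe: float = PROBE_RADIUS,
    density: float = POINT_DENSITY,
    seed: int | None = None,
    frame: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic spherical-lattice points just outside the surface.

    Each heavy atom is decorated with a Fibonacci lattice on a sphere of
    radius ``r_vdw + 2*probe`` at the target areal density; points that
    fall inside another atom's expanded sphere (buried points) are
    removed.  ``frame`` rotates the lattices (pass the structure's
    canonical frame for rigid-motion equivariance); ``seed`` adds a
    reproducible extra rotation.  Genuine triangulation vertices from an
    external surface program can be substituted for this generator
    anywhere a point field is accepted.
    """
    if elements is None:
        atoms = list(atoms_or_coords)
        if not atoms:
            raise ValueError("no atoms to build a surface around")
        coords = np.array([a.coords for a in atoms], dtype=float)
        radii = np.array([vdw_radius(a.element) for a in atoms])
    else:
        coords = np.asarray(atoms_or_coords, dtype=float).reshape(-1, 3)
        if coords.size == 0:
            raise ValueError("no atoms to build a surface around")
        radii = np.array([vdw_radius(e) for e in elements])

    rot = np.eye(3) if frame is None else np.asarray(frame, dtype=float)
    if seed is not None:
        rng = np.random.default_rng(seed)
        extra = rng.standard_normal((3, 3))
        q, _ = np.linalg.qr(extra)
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        rot = rot @ q

    expanded = radii + 2.0 * probe
    tree = cKDTree(coords)
    out = []
    for i, (c, r_exp) in enumerate(zip(coords, expanded)):
        n_pts = max(int(math.ceil(4.0 * math.pi * r_exp ** 2 * density)), 1)
        pts = c + r_exp * (_fibonacci_sphere(n_pts) @ rot.T)
        neigh = tree.query_ball_point(c, r=r_exp + expanded.max())
        keep = np.ones(len(pts), dtype=bool)
        for j in neigh:
            if j == i:
                continue
            keep &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j] - 1e-9
        out.append(pts[keep])
    points = np.vstack(out) if out else np.empty((0, 3))
    return points


def select_high_dx(dx_values: np.ndarray, threshold_quantile: float = EVD_QUANTILE) -> np.ndarray:
    """Boolean mask of points in the upper tail of a Gumbel fit to D_x.

    Location/scale are fit by maximum likelihood; a point is selected
    when the fitted CDF at its D_x is >= ``threshold_quantile`` (default
    0.96, i.e. roughly the top 4% of a well-fit field).
    """
    dx = np.asarray(dx_values, dtype=float)
    if dx.size < 2 or np.ptp(dx) == 0:
        raise DegenerateFieldError("constant D_x field: cannot fit a tail threshold")
    if dx.size < 30:
        logger.warning("only %d D_x values: extreme-value fit may be unstable", dx.size)
    loc, scale = stats.gumbel_r.fit(dx)
    return stats.gumbel_r.cdf(dx, loc=loc, scale=scale) >= threshold_quantile


def cluster_points(
    points: np.ndarray,
    eps: float = CLUSTER_EPS,
    min_pts: int = CLUSTER_MIN_PTS,
) -> np.ndarray:
    """Density-cluster selected points; label -1 marks unclustered (XX).

    OPTICS reachabilities are extracted DBSCAN-style at the single
    threshold ``eps``; clusters need at least ``min_pts`` members.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < min_pts:
        return np.full(len(points), -1, dtype=int)
    model = OPTICS(min_samples=min_pts, max_eps=eps, eps=eps, cluster_method="dbscan")
    labels = model.fit_predict(points)
    # guard: drop any cluster that ends up under the size floor
    for lab in set(labels) - {-1}:
        if np.sum(labels == lab) < min_pts:
            labels[labels == lab] = -1
    return labels


def define_sites(
    domain: DomainStructure,
    points: np.ndarray,
    dx: np.ndarray,
    labels: np.ndarray,
    cutoff: float = SITE_CUTOFF,
) -> list[DPASite]:
    """Residues within ``cutoff`` of each cluster, ranked by mean D_x.

    The top-ranked site gets letter O, the next P, and so on.  A residue
    close to several clusters belongs to each of their sites.  Clusters
    touching no residue are dropped with a warning.
    """
    heavy = domain.heavy_coords()
    keys = domain.residue_of_heavy_atom()
    tree = cKDTree(heavy)
    ranked = []
    for lab in sorted(set(labels.tolist()) - {-1}):
        idx = np.where(labels == lab)[0]
        hits = tree.query_ball_point(points[idx], r=cutoff)
        residues = frozenset(keys[j] for h in hits for j in h)
        mean_dx = float(np.mean(dx[idx]))
        if not residues:
            logger.warning("cluster %d touches no residue; dropped", lab)
            continue
        ranked.append((mean_dx, idx, residues))
    ranked.sort(key=lambda t: -t[0])
    return [
        DPASite(SITE_LETTERS[i], residues, mean_dx, idx)
        for i, (mean_dx, idx, residues) in enumerate(ranked)
    ]


def predict_sites(
    domain: DomainStructure,
    r_c: float = R_C_DEFAULT,
    r_s: float = R_S_DEFAULT,
    gamma_s_ratio: float = GAMMA_S_RATIO,
    probe: float = PROBE_RADIUS,
    density: float = POINT_DENSITY,
    quantile: float = EVD_QUANTILE,
    eps: float = CLUSTER_EPS,
    min_pts: int = CLUSTER_MIN_PTS,
    seed: int | None = None,
    nodes: str = "ca",
    direction: str = "m_to_0",
) -> SurfacePointField:
    """Run the full DPA pipeline on one domain.

    ``nodes`` selects the elastic-network nodes: ``"ca"`` (default, one
    node per residue) or ``"heavy"`` (every heavy atom).  The result
    carries the point field with labels and the ranked sites.
    """
    if nodes == "ca":
        node_coords = domain.ca_coords()
    elif nodes == "heavy":
        node_coords = domain.heavy_coords()
    else:
        raise ValueError(f"unknown node selection {nodes!r}")
    enm = build_enm(node_coords, r_c=r_c)
    engine = DPAEngine(enm, r_s=r_s, gamma_s_ratio=gamma_s_ratio, direction=direction)

    atoms = domain.heavy_atoms()
    _, frame = canonical_frame(np.array([a.coords for a in atoms]))
    points = generate_surface_points(atoms, probe=probe, density=density,
                                     seed=seed, frame=frame)
    dx = engine.field(points)
    mask = select_high_dx(dx, threshold_quantile=quantile)

    labels_full = np.full(len(points), -2, dtype=int)  # -2: below threshold
    sel_idx = np.where(mask)[0]
    sel_labels = cluster_points(points[sel_idx], eps=eps, min_pts=min_pts)
    labels_full[sel_idx] = sel_labels

    sites = define_sites(domain, points, dx, np.where(labels_full >= 0, labels_full, -1))

    letter_of_cluster: dict[int, str] = {}
    for site in sites:
        lab = int(labels_full[site.point_indices[0]])
        letter_of_cluster[lab] = site.site_label
    out_labels = []
    for lab in labels_full:
        if lab == -2:
            out_labels.append("NN")
        elif lab == -1 or lab not in letter_of_cluster:
            out_labels.append("XX")
        else:
            out_labels.append(letter_of_cluster[lab])
    return SurfacePointField(points=points, dx=dx, labels=out_labels, sites=sites)
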