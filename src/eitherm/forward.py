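"""Quasi-static FEM forward solver, Jacobian and measurement model.

Solves the conduction problem ``div(sigma grad u) = 0`` with point-electrode
current injection (linear P1 elements on tetrahedra), extracts differential
voltages for a pairwise drive / adjacent-measurement protocol, computes the
adjoint sensitivity (Jacobian) of the voltages with respect to per-element
conductivity, and models additive measurement noise at a prescribed SNR.

One sparse factorization of the grounded system matrix serves every
injection and measurement field at a given conductivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import ConductivityField, TetMesh

__all__ = [
    "StimulationPattern",
    "MeasurementFrame",
    "JacobianMatrix",
    "build_pattern",
    "assemble_conductance",
    "ForwardOperator",
    "solve_forward",
    "compute_jacobian",
    "transfer_impedance_matrix",
    "add_measurement_noise",
]


@dataclass(frozen=True)
class StimulationPattern:
    """Current-injection protocol with adjacent voltage measurements.

    ``injections`` is a list of electrode-index pairs; for each injection,
    ``measurements`` holds the adjacent electrode pairs whose electrodes are
    both non-injecting for that injection.
    """

    n_electrodes: int
    injections: tuple  # ((e+, e-), ...)
    measurements: tuple  # per injection: ((m+, m-), ...)
    current: float = 1e-3

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for m in self.measurements)

    def flat(self):
        """Iterate (injection_index, (e+, e-), (m+, m-)) in frame order."""
        for i, (inj, meas) in enumerate(zip(self.injections, self.measurements)):
            for pair in meas:
                yield i, inj, pair

    def measurement_pairs(self) -> list:
        """Distinct measurement pairs used anywhere in the pattern."""
        seen: dict = {}
        for _, _, pair in self.flat():
            seen.setdefault(pair, None)
        return list(seen)


def build_pattern(n_electrodes: int = 16, injection_offset: int = 7,
                  current: float = 1e-3) -> StimulationPattern:
    """Offset-pair injection with all-adjacent-pair measurements.

    Injections are ``(i, (i+offset) mod n)`` for every electrode i; the
    measurements for each injection are the adjacent pairs ``(j, j+1 mod n)``
    not touching either injection electrode.  For 16 electrodes and offset 7
    this yields 16 x 12 = 192 measurements.
    """
    n = n_electrodes
    if n < 3:
        raise ValueError("need at least 3 electrodes")
    if not (2 <= injection_offset <= n - 2):
        raise ValueError("injection offset must avoid adjacent electrode pairs")
    injections = []
    measurements = []
    for i in range(n):
        inj = (i, (i + injection_offset) % n)
        pairs = tuple(
            (j, (j + 1) % n)
            for j in range(n)
            if j not in inj and (j + 1) % n not in inj
        )
        injections.append(inj)
        measurements.append(pairs)
    return StimulationPattern(n, tuple(injections), tuple(measurements), current)


@dataclass
class MeasurementFrame:
    """Differential electrode voltages (V) in pattern order."""

    values: np.ndarray
    pattern: StimulationPattern
    frequency_tag: str = "lf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.pattern.n_measurements:
            raise ValueError("frame length does not match pattern measurement count")

    def copy(self) -> "MeasurementFrame":
        return MeasurementFrame(self.values.copy(), self.pattern, self.frequency_tag)


@dataclass
class JacobianMatrix:
    """Sensitivity of differential voltages to element conductivities.

    ``entries[m, e] = d v_m / d sigma_e`` (V per (S/m)), linearized at
    ``sigma``.
    """

    entries: np.ndarray
    pattern: StimulationPattern
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("Jacobian contains non-finite entries")


def assemble_conductance(mesh: TetMesh, sigma: ConductivityField,
                         ground_node: Optional[int] = None):
    """Assemble the P1 stiffness matrix for ``div(sigma grad u)``.

    Returns ``(A_grounded, A_free, ground_node)``: the symmetric system with
    one reference node grounded (row/column cleared, unit diagonal) and the
    pure-Neumann operator.  Rows of the free operator sum to zero.
    """
    g = mesh.shape_gradients()  # (n_e, 4, 3)
    w = sigma.values * mesh.volumes  # (n_e,)
    local = np.einsum("e,eik,ejk->eij", w, g, g)  # (n_e, 4, 4)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    A = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    if ground_node is None:
        ground_node = int(np.argmin(
            np.linalg.norm(mesh.node_coords - mesh.node_coords.mean(axis=0), axis=1)
        ))
    Ag = A.tolil(copy=True)
    Ag[ground_node, :] = 0.0
    Ag[:, ground_node] = 0.0
    Ag[ground_node, ground_node] = 1.0
    Ag = Ag.tocsc()
    # nodes floating in zero-conductivity regions (every incident element
    # has sigma = 0) get a pinned potential; a floating electrode is an
    # unsolvable measurement setup and is reported instead
    floating = np.flatnonzero(Ag.diagonal() == 0.0)
    if len(floating):
        if set(floating) & set(mesh.electrode_nodes):
            raise RuntimeError("electrode disconnected from the conducting domain")
        pin = sp.coo_matrix((np.ones(len(floating)), (floating, floating)),
                            shape=Ag.shape)
        Ag = (Ag + pin).tocsc()
    return Ag, A, ground_node


class ForwardOperator:
    """Factorized forward solver at a fixed conductivity.

    Caches electrode unit-current fields so that solving the forward problem
    and assembling the adjoint Jacobian share factorization work.
    """

    def __init__(self, mesh: TetMesh, sigma: ConductivityField,
                 ground_node: Optional[int] = None):
        if not mesh.electrode_nodes:
            raise ValueError("mesh has no electrodes; call place_electrodes first")
        self.mesh = mesh
        self.sigma = sigma
        self.A, self.A_free, self.ground_node = assemble_conductance(mesh, sigma, ground_node)
        try:
            self._lu = spla.splu(self.A)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise RuntimeError(f"forward system is singular: {exc}") from exc
        self._unit_fields: dict = {}

    def _solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs = rhs.copy()
        rhs[self.ground_node] = 0.0
        u = self._lu.solve(rhs)
        res = np.linalg.norm(self.A @ u - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and res > 1e-8 * scale:
            raise RuntimeError(f"forward solve residual {res:.3g} exceeds tolerance")
        return u

    def electrode_field(self, pos: int, neg: int, current: float = 1.0) -> np.ndarray:
        """Nodal potentials for ``current`` injected electrode pos -> neg."""
        key = (pos, neg)
        if key not in self._unit_fields:
            rhs = np.zeros(self.mesh.n_nodes)
            rhs[self.mesh.electrode_nodes[pos]] = 1.0
            rhs[self.mesh.electrode_nodes[neg]] = -1.0
            self._unit_fields[key] = self._solve(rhs)
        return self._unit_fields[key] * current

    def voltages(self, pattern: StimulationPattern,
                 frequency_tag: Optional[str] = None) -> MeasurementFrame:
        out = np.empty(pattern.n_measurements)
        nodes = self.mesh.electrode_nodes
        for m, (_, inj, pair) in enumerate(pattern.flat()):
            u = self.electrode_field(*inj, current=pattern.current)
            out[m] = u[nodes[pair[0]]] - u[nodes[pair[1]]]
        return MeasurementFrame(out, pattern,
                                frequency_tag or self.sigma.frequency_tag)

    def jacobian(self, pattern: StimulationPattern) -> JacobianMatrix:
        """Adjoint Jacobian: ``J[m, e] = -V_e grad(u_drive) . grad(u_meas)``.

        ``u_drive`` is the field of the injection at the pattern current and
        ``u_meas`` the field of unit current through the measurement pair;
        this is the exact derivative of the discrete P1 system.
        """
        mesh = self.mesh
        G = mesh.shape_gradients()
        vols = mesh.volumes

        def elem_grads(u: np.ndarray) -> np.ndarray:
            return np.einsum("ei,eik->ek", u[mesh.tets], G)

        drive_grads = {inj: elem_grads(self.electrode_field(*inj, current=pattern.current))
                       for inj in pattern.injections}
        meas_grads = {pair: elem_grads(self.electrode_field(*pair, current=1.0))
                      for pair in pattern.measurement_pairs()}
        J = np.empty((pattern.n_measurements, mesh.n_elements))
        for m, (_, inj, pair) in enumerate(pattern.flat()):
            J[m] = -vols * np.einsum("ek,ek->e", drive_grads[inj], meas_grads[pair])
        return JacobianMatrix(J, pattern, self.sigma.values.copy())


def solve_forward(mesh: TetMesh, sigma: ConductivityField,
                  pattern: StimulationPattern) -> MeasurementFrame:
    """Differential voltages of the pattern at conductivity ``sigma``."""
    return ForwardOperator(mesh, sigma).voltages(pattern)


def compute_jacobian(mesh: TetMesh, sigma: ConductivityField,
                     pattern: StimulationPattern) -> JacobianMatrix:
    """Adjoint Jacobian of the pattern voltages at ``sigma``."""
    return ForwardOperator(mesh, sigma).jacobian(pattern)


def transfer_impedance_matrix(mesh: TetMesh, sigma: ConductivityField,
                              electrodes: Optional[Sequence[int]] = None) -> np.ndarray:
    """Pairwise transfer impedances ``Z[i, j] = (u_i - u_j)/I`` (Ohm).

    Unit current is injected i -> j; the matrix is symmetric with a zero
    diagonal by convention.
    """
    if electrodes is not None:
        mesh.electrode_nodes = list(electrodes)
    if len(mesh.electrode_nodes) < 2:
        raise ValueError("need at least two electrodes")
    op = ForwardOperator(mesh, sigma)
    nodes = list(mesh.electrode_nodes)
    n = len(nodes)
    # superposition: field for injection i->j is u_i - u_j with u_k the
    # field of unit current at electrode k returned at electrode 0
    fields = [op.electrode_field(k, 0, 1.0) if k else np.zeros(mesh.n_nodes)
              for k in range(n)]
    Z = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u = fields[i] - fields[j]
            Z[i, j] = Z[j, i] = u[nodes[i]] - u[nodes[j]]
    return Z


def add_measurement_noise(v: MeasurementFrame, vref: MeasurementFrame,
                          snr_db: float, seed=None) -> MeasurementFrame:
    """Add zero-mean Gaussian noise at an SNR defined on the voltage change.

    The noise standard deviation is ``rms(v - vref) / 10^(snr_db/20)``
    (SNR referenced to the heating-induced differential signal, not the
    absolute voltages); noise is added to ``v`` only.
    """
    if v.pattern is not vref.pattern and v.pattern != vref.pattern:
        raise ValueError("frames must share a stimulation pattern")
    dv = v.values - vref.values
    rms = float(np.sqrt(np.mean(dv ** 2)))
    if rms == 0.0:
        raise ValueError("rms voltage change is zero; SNR undefined")
    if np.isinf(snr_db):
        return v.copy()
    sigma_n = rms / 10.0 ** (snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = v.values + rng.normal(0.0, sigma_n, size=len(v.values))
    return MeasurementFrame(noisy, v.pattern, v.frequency_tag)
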