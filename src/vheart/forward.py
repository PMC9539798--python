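"""Forward computation of extracellular potentials.

Three routes from transmembrane voltage to electrograms:

* **Lead fields** — for every electrode a reciprocal scalar field Z_e is
  precomputed once by injecting unit current at the electrode and
  withdrawing it at the RL ground on the torso volume conductor (linear
  tetrahedral FEM, piecewise-constant conductivity per tissue label).
  The ECG is then the bilinear form phi_e(t) = -Z_e' K_i Vm(t), i.e. the
  volume integral -int grad Z_e . (sigma_i grad Vm) dV over the heart.
* **Pseudo-bidomain recovery** — at selected instants the elliptic
  problem div((sigma_i+sigma_e) grad phi) = -div(sigma_i grad Vm) is
  solved on the torso mesh (RL-pinned gauge), yielding body-surface
  potential maps and intracardiac electrograms.
* **Pseudo-ECG** — the infinite-medium integral
  phi = 1/(4 pi sigma_b) int grad Vm . grad(1/r) dV, a fast cross-check.

Intracellular conductivity defaults to 0.174 S/m longitudinal / 0.019 S/m
transverse (standard literature values); pure scaling of sigma_i rescales
ECG amplitude only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .anatomy import CONDUCTIVITY_S_PER_M, ElectrodeSet, TorsoModel
from .mesh import CONDUCTING, VolumetricMesh, boundary_faces

MM_TO_M = 1e-3
MV_TO_V = 1e-3

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
PRECORDIAL = ("V1", "V2", "V3", "V4", "V5", "V6")
STANDARD_LEADS = LIMB_LEADS + PRECORDIAL


@dataclass(frozen=True)
class ConductivityConfig:
    """Volume-conductor conductivities (S/m)."""

    #: isotropic passive tissues by label
    passive: dict = field(default_factory=lambda: dict(CONDUCTIVITY_S_PER_M))
    sigma_i_longitudinal: float = 0.174
    sigma_i_transverse: float = 0.019
    #: extracellular conductivity inside myocardium (isotropic)
    sigma_e_myocardium: float = 0.22
    #: bulk conductivity for the infinite-medium pseudo-ECG
    sigma_bulk: float = 0.22


# --------------------------------------------------------------------------
# linear tetrahedral FEM
# --------------------------------------------------------------------------

def _element_gradients(nodes_m: np.ndarray, elems: np.ndarray):
    """P1 shape-function gradients (m^-1) and element volumes (m^3)."""
    p = nodes_m[elems]                      # (m, 4, 3)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    v3 = p[:, 3] - p[:, 0]
    vol6 = np.einsum("ij,ij->i", np.cross(v1, v2), v3)
    grads = np.empty((len(elems), 4, 3))
    # gradients of barycentric coordinates
    grads[:, 1] = np.cross(v2, v3) / vol6[:, None]
    grads[:, 2] = np.cross(v3, v1) / vol6[:, None]
    grads[:, 3] = np.cross(v1, v2) / vol6[:, None]
    grads[:, 0] = -(grads[:, 1] + grads[:, 2] + grads[:, 3])
    return grads, np.abs(vol6) / 6.0


def element_conductivities(mesh: VolumetricMesh, cond: ConductivityConfig,
                           kind: str = "total") -> np.ndarray:
    """Per-element 3x3 conductivity tensors (S/m).

    ``kind='total'`` builds the volume-conductor operator: isotropic
    passive tissues plus sigma_i + sigma_e on myocardium (used by the
    lead-field and recovery solves).  ``kind='intracellular'`` builds the
    source operator: the fiber-aligned sigma_i tensor on myocardium and
    zero everywhere else (blood, lungs, torso carry no membrane sources).
    """
    if kind not in ("total", "intracellular"):
        raise ValueError(f"unknown conductivity kind {kind!r}")
    m = mesh.n_elements
    sig = np.zeros((m, 3, 3))
    eye = np.eye(3)
    if kind == "total":
        for lab, s in cond.passive.items():
            sig[mesh.element_labels == int(lab)] = s * eye
    myo = mesh.label_mask(CONDUCTING)
    if myo.any():
        f = mesh.element_fibers[myo][:, 0, :]
        sl, st = cond.sigma_i_longitudinal, cond.sigma_i_transverse
        block = st * eye + (sl - st) * np.einsum("ei,ej->eij", f, f)
        if kind == "total":
            block = block + cond.sigma_e_myocardium * eye
        sig[myo] = block
    return sig


def assemble_stiffness(mesh: VolumetricMesh, sigma: np.ndarray) -> csr_matrix:
    """K[i,j] = int grad N_i . (sigma grad N_j) dV  (SI units)."""
    grads, vol = _element_gradients(mesh.nodes * MM_TO_M, mesh.elements)
    ke = np.einsum("eai,eij,ebj->eab", grads, sigma, grads) * vol[:, None, None]
    rows = np.repeat(mesh.elements, 4, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 4)).ravel()
    n = mesh.n_nodes
    return coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


class TorsoFEM:
    """Factorized torso operator shared by lead fields and recovery."""

    def __init__(self, torso: TorsoModel, cond: ConductivityConfig | None = None):
        self.torso = torso
        self.cond = cond or ConductivityConfig()
        mesh = torso.mesh
        sigma = element_conductivities(mesh, self.cond)
        self.K = assemble_stiffness(mesh, sigma)
        self.ground = torso.electrodes["RL"]
        # pin the RL ground node (gauge)
        K = self.K.tolil()
        K[self.ground, :] = 0.0
        K[:, self.ground] = 0.0
        K[self.ground, self.ground] = 1.0
        self._lu = splu(K.tocsc())

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs = rhs.copy()
        rhs[self.ground] = 0.0
        return self._lu.solve(rhs)


@dataclass
class LeadFieldSet:
    """Reciprocal fields Z_e on the torso mesh, plus heart-node samples."""

    electrodes: list                 # electrode names (excluding ground)
    z_torso: np.ndarray              # (n_e, n_torso_nodes)
    z_heart: np.ndarray | None = None  # (n_e, n_heart_nodes)
    ground: str = "RL"


def compute_lead_fields(fem: TorsoFEM,
                        electrodes: ElectrodeSet | None = None) -> LeadFieldSet:
    """Solve the reciprocal problem for every electrode against RL.

    Unit current is injected at the electrode node and withdrawn at the
    ground; Z_RL is identically zero by the pinned gauge.
    """
    electrodes = electrodes or fem.torso.electrodes
    names = [n for n in electrodes.names if n != "RL"]
    n = fem.torso.mesh.n_nodes
    z = np.empty((len(names), n))
    for k, name in enumerate(names):
        rhs = np.zeros(n)
        rhs[electrodes[name]] = 1.0
        rhs[fem.ground] -= 1.0
        z[k] = fem.solve(rhs)
    return LeadFieldSet(electrodes=names, z_torso=z)


def heart_torso_projector(torso: TorsoModel,
                          heart_mesh: VolumetricMesh) -> csr_matrix:
    """Sparse trilinear interpolation matrix P: heart nodes <- torso nodes.

    Built on the torso voxel lattice; P carries lead fields onto the
    heart (``Z_heart = P Z_torso``) and, transposed, Galerkin-projects
    the fine-mesh source functional onto the torso basis, keeping both
    forward routes source-consistent.
    """
    grid = torso.mesh.grid
    origin, h = np.asarray(grid["origin"]), grid["spacing"]
    nshape = tuple(s + 1 for s in grid["shape"])
    node_id = np.full(nshape, -1, dtype=np.int64)
    ijk = np.round((torso.mesh.nodes - origin) / h).astype(int)
    node_id[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.arange(torso.mesh.n_nodes)

    loc = (heart_mesh.nodes - origin) / h
    cell = np.floor(loc).astype(int)
    for d in range(3):
        cell[:, d] = np.clip(cell[:, d], 0, nshape[d] - 2)
    frac = loc - cell

    kd = None
    rows, cols, vals = [], [], []
    for corner in range(8):
        off = np.array([(corner >> d) & 1 for d in range(3)])
        w = np.prod(np.where(off[None, :] == 1, frac, 1.0 - frac), axis=1)
        ids = node_id[cell[:, 0] + off[0], cell[:, 1] + off[1],
                      cell[:, 2] + off[2]]
        ok = ids >= 0
        rows.append(np.flatnonzero(ok))
        cols.append(ids[ok])
        vals.append(w[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    P = coo_matrix((vals, (rows, cols)),
                   shape=(heart_mesh.n_nodes, torso.mesh.n_nodes)).tocsr()
    # renormalize rows with missing corners; nearest-node fallback
    rowsum = np.asarray(P.sum(axis=1)).ravel()
    missing = rowsum < 1e-9
    good = ~missing
    scale = np.ones_like(rowsum)
    scale[good] = 1.0 / rowsum[good]
    P = csr_matrix(P.multiply(scale[:, None]))
    if missing.any():
        if kd is None:
            kd = cKDTree(torso.mesh.nodes)
        _, nn = kd.query(heart_mesh.nodes[missing])
        fix = coo_matrix((np.ones(int(missing.sum())),
                          (np.flatnonzero(missing), nn)), shape=P.shape)
        P = csr_matrix(P + fix)
    return P


def sample_leadfields_on_heart(lf: LeadFieldSet, torso: TorsoModel,
                               heart_mesh: VolumetricMesh,
                               projector: csr_matrix | None = None
                               ) -> LeadFieldSet:
    """Interpolate Z_e from the torso voxel lattice onto heart nodes."""
    P = (heart_torso_projector(torso, heart_mesh)
         if projector is None else projector)
    zh = (P @ lf.z_torso.T).T
    return LeadFieldSet(electrodes=lf.electrodes, z_torso=lf.z_torso,
                        z_heart=zh, ground=lf.ground)


# --------------------------------------------------------------------------
# ECG recording and lead algebra
# --------------------------------------------------------------------------

@dataclass
class ECGRecording:
    """Named lead traces in mV at a fixed sampling interval."""

    leads: dict                     # name -> (n_t,) array, mV
    times: np.ndarray               # ms

    @property
    def fs_hz(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])

    @property
    def lead_names(self):
        return list(self.leads)

    def copy(self) -> "ECGRecording":
        return ECGRecording({k: v.copy() for k, v in self.leads.items()},
                            self.times.copy())

    def stack(self, names=None) -> np.ndarray:
        names = names or self.lead_names
        return np.stack([self.leads[n] for n in names])

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"time_ms": self.times})
        for name, tr in self.leads.items():
            df[name] = tr
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ECGRecording":
        import pandas as pd
        df = pd.read_csv(path)
        times = df["time_ms"].to_numpy(float)
        leads = {c: df[c].to_numpy(float) for c in df.columns if c != "time_ms"}
        return cls(leads=leads, times=times)


def twelve_lead_from_potentials(phi: dict, times: np.ndarray) -> ECGRecording:
    """Standard 12-lead algebra from electrode potentials (vs RL ground).

    Einthoven: I = LA-RA, II = LL-RA, III = LL-LA (so I + III = II
    exactly); Goldberger augmented leads; Wilson central terminal for the
    precordial leads.
    """
    ra, la, ll = phi["RA"], phi["LA"], phi["LL"]
    wct = (ra + la + ll) / 3.0
    lead_i = la - ra
    lead_ii = ll - ra
    leads = {
        "I": lead_i,
        "II": lead_ii,
        "III": lead_ii - lead_i,   # Einthoven identity exact by construction
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for v in PRECORDIAL:
        leads[v] = phi[v] - wct
    return ECGRecording(leads=leads, times=times)


class ECGForwardOperator:
    """Precomputed lead vectors: phi_e(t) = L_e . Vm(t) on the heart mesh."""

    def __init__(self, lf: LeadFieldSet, heart_mesh: VolumetricMesh,
                 cond: ConductivityConfig | None = None):
        if lf.z_heart is None:
            raise ValueError("lead fields not sampled on the heart mesh "
                             "(run sample_leadfields_on_heart)")
        cond = cond or ConductivityConfig()
        sigma_i = element_conductivities(heart_mesh, cond,
                                         kind="intracellular")
        k_i = assemble_stiffness(heart_mesh, sigma_i)
        # phi_e = -Z_e' K_i Vm   (V; traces arrive in mV)
        self.L = -(lf.z_heart @ k_i)
        self.electrodes = list(lf.electrodes)

    def potentials(self, vm_mv: np.ndarray) -> np.ndarray:
        """Raw electrode potentials vs ground, mV, shape (n_e, n_t)."""
        if vm_mv.shape[0] != self.L.shape[1]:
            raise ValueError("Vm trace set does not match the heart mesh")
        return self.L @ vm_mv.astype(np.float64)

    def __call__(self, vm_mv: np.ndarray, times: np.ndarray) -> ECGRecording:
        phi = self.potentials(vm_mv)
        pots = {name: phi[k] for k, name in enumerate(self.electrodes)}
        return twelve_lead_from_potentials(pots, times)


def ecg_from_leadfields(lf: LeadFieldSet, vm_traces, heart_mesh,
                        cond: ConductivityConfig | None = None) -> ECGRecording:
    """One-shot 12-lead ECG from lead fields and a VmTraceSet."""
    op = ECGForwardOperator(lf, heart_mesh, cond)
    return op(vm_traces.vm, vm_traces.times)


# --------------------------------------------------------------------------
# pseudo-ECG (infinite medium)
# --------------------------------------------------------------------------

class PseudoECGOperator:
    """phi(t) = 1/(4 pi sigma_b) int grad Vm . grad(1/r) dV per electrode."""

    def __init__(self, heart_mesh: VolumetricMesh, electrode_xyz_mm: np.ndarray,
                 sigma_bulk: float = 0.22):
        mask = heart_mesh.label_mask(CONDUCTING)
        elems = heart_mesh.elements[mask]
        grads, vol = _element_gradients(heart_mesh.nodes * MM_TO_M, elems)
        cent = heart_mesh.nodes[elems].mean(axis=1) * MM_TO_M
        ex = np.atleast_2d(np.asarray(electrode_xyz_mm, float)) * MM_TO_M
        n = heart_mesh.n_nodes
        self.W = np.zeros((len(ex), n))
        for k, e in enumerate(ex):
            r = cent - e[None, :]
            d = np.linalg.norm(r, axis=1)
            # sign convention matches the reciprocal lead-field route
            # (Z = 1/(4 pi sigma r) for the infinite medium)
            w_e = np.einsum("eai,ei,e->ea", grads, r / d[:, None] ** 3, vol)
            np.add.at(self.W[k], elems.ravel(),
                      (w_e / (4.0 * np.pi * sigma_bulk)).ravel())
        self.sigma_bulk = sigma_bulk

    def __call__(self, vm_mv: np.ndarray) -> np.ndarray:
        return self.W @ vm_mv.astype(np.float64)


def pseudo_ecg(vm_traces, heart_mesh, electrode_xyz_mm,
               sigma_bulk: float = 0.22) -> np.ndarray:
    """Infinite-medium pseudo-electrogram trace(s), arbitrary mV-scale."""
    op = PseudoECGOperator(heart_mesh, electrode_xyz_mm, sigma_bulk)
    return op(vm_traces.vm)


def infinite_medium_leadfields(heart_mesh: VolumetricMesh, electrode_xyz_mm,
                               names=None,
                               sigma_bulk: float = 0.22) -> LeadFieldSet:
    """Analytic unbounded-medium lead fields Z = 1/(4 pi sigma r).

    Sampled at heart nodes; pairing these with a unit-isotropic source
    tensor in :class:`ECGForwardOperator` reproduces the pseudo-ECG
    integral through the bilinear lead-field machinery — the
    dual-implementation cross-check of the two forward routes.
    """
    ex = np.atleast_2d(np.asarray(electrode_xyz_mm, float)) * MM_TO_M
    names = list(names) if names is not None else [
        f"E{k}" for k in range(len(ex))]
    pts = heart_mesh.nodes * MM_TO_M
    z = np.empty((len(ex), heart_mesh.n_nodes))
    for k, e in enumerate(ex):
        r = np.linalg.norm(pts - e[None, :], axis=1)
        z[k] = 1.0 / (4.0 * np.pi * sigma_bulk * np.maximum(r, 1e-6))
    return LeadFieldSet(electrodes=names, z_torso=z, z_heart=z, ground="inf")


# --------------------------------------------------------------------------
# pseudo-bidomain extracellular recovery
# --------------------------------------------------------------------------

@dataclass
class ExtracellularSolution:
    sample_times: np.ndarray          # ms
    phi_torso: np.ndarray             # (n_samples, n_torso_nodes) mV
    surface_nodes: np.ndarray         # torso-surface node indices (BSPM)

    def bspm(self) -> np.ndarray:
        return self.phi_torso[:, self.surface_nodes]

    def egm(self, node_indices) -> np.ndarray:
        return self.phi_torso[:, np.asarray(node_indices, int)]


def recover_extracellular(fem: TorsoFEM, heart_mesh: VolumetricMesh,
                          vm_traces, sample_times_ms,
                          cond: ConductivityConfig | None = None,
                          projector: csr_matrix | None = None
                          ) -> ExtracellularSolution:
    """Elliptic pseudo-bidomain recovery at selected instants.

    Solves div((sigma_i+sigma_e) grad phi) = -div(sigma_i grad Vm) on the
    torso mesh with the RL-pinned gauge.  The membrane source functional
    is assembled on the fine heart mesh (-K_i Vm) and Galerkin-projected
    onto the torso basis through the trilinear projector, so both forward
    routes see the same cardiac sources.
    """
    cond = cond or ConductivityConfig()
    torso_mesh = fem.torso.mesh
    sample_times_ms = np.atleast_1d(np.asarray(sample_times_ms, float))
    if (sample_times_ms.min() < vm_traces.times[0]
            or sample_times_ms.max() > vm_traces.times[-1]):
        raise ValueError("sample time outside the simulated beat")

    P = (heart_torso_projector(fem.torso, heart_mesh)
         if projector is None else projector)
    sigma_i = element_conductivities(heart_mesh, cond, kind="intracellular")
    k_i = assemble_stiffness(heart_mesh, sigma_i)
    PtKi = (P.T @ k_i).tocsr()

    phi = np.empty((len(sample_times_ms), torso_mesh.n_nodes))
    for k, ts in enumerate(sample_times_ms):
        i = int(np.argmin(np.abs(vm_traces.times - ts)))
        rhs = -(PtKi @ (vm_traces.vm[:, i].astype(np.float64) * MV_TO_V))
        phi[k] = fem.solve(rhs) / MV_TO_V
    surface = np.unique(boundary_faces(torso_mesh))
    return ExtracellularSolution(sample_times=sample_times_ms, phi_torso=phi,
                                 surface_nodes=surface)


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def filter_ecg(rec: ECGRecording, lowpass_hz: float = 150.0,
               highpass_hz: float = 0.5,
               notch_hz: float | None = None) -> ECGRecording:
    """Zero-phase Butterworth filtering (3rd order) plus optional notch.

    Defaults follow the simulated-signal chain (150 Hz low-pass, 0.5 Hz
    high-pass); the 50 Hz band-stop is for measured inputs.
    """
    fs = rec.fs_hz
    out = rec.copy()
    sos_lp = sp_signal.butter(3, lowpass_hz, "low", fs=fs, output="sos")
    sos_hp = sp_signal.butter(3, highpass_hz, "high", fs=fs, output="sos")
    for name, tr in out.leads.items():
        x = sp_signal.sosfiltfilt(sos_lp, tr)
        x = sp_signal.sosfiltfilt(sos_hp, x)
        if notch_hz is not None:
            b, a = sp_signal.iirnotch(notch_hz, Q=30.0, fs=fs)
            x = sp_signal.filtfilt(b, a, x)
        out.leads[name] = x
    return out
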