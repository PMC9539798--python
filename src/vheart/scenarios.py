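"""End-to-end scenario orchestration.

A :class:`Pipeline` builds the synthetic anatomy, torso, lead fields and
conduction system once, tunes the AV node against the PR target on the
sinus rhythm, and then runs scenarios (sinus, complete LBBB/RBBB, each
under normal or reduced conduction velocity) reusing the precomputed
artifacts — tuning and lead fields are never recomputed for pathologies.
The sinus-derived repolarization (tau_close) field is reused in every
pathology: all electrophysiology other than the block and the optional
CV reduction is identical to sinus.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .activation import (ActivationMap, EikonalSolver, StimulusProtocol,
                         TissueEP, solve_coupled)
from .anatomy import (HeartConfig, HeartModel, TorsoConfig, TorsoModel,
                      build_heart, build_torso)
from .conduction import (BranchConfig, ConductionSystem, attach_avn,
                         grow_tree, tune_avn_cv, tune_terminal_cvs)
from .forward import (ConductivityConfig, ECGForwardOperator, ECGRecording,
                      LeadFieldSet, TorsoFEM, compute_lead_fields, filter_ecg,
                      sample_leadfields_on_heart)
from .membrane import (MSParams, RepolConfig, VmTraceSet, reaction_eikonal_vm,
                       ventricular_repolarization_fields)
from .analysis import IntervalReport, measure_intervals
from .mesh import Tissue, VENTRICULAR

REDUCED_CV_M_PER_S = 0.3


@dataclass(frozen=True)
class Scenario:
    """One simulated beat: rhythm, block and CV condition."""

    rhythm: str = "sinus"            # 'sinus' | 'paced'
    block: str = "none"              # 'none' | 'left' | 'right'
    cv_mode: str = "normal"          # 'normal' | 'reduced'
    beat_ms: float = 700.0
    baseline_ms: float = 25.0
    seed: int = 0
    pacing_sources: tuple = ()       # (node, onset_ms) pairs for 'paced'

    def __post_init__(self):
        if self.rhythm not in ("sinus", "paced"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")
        if self.block not in ("none", "left", "right"):
            raise ValueError(f"unknown block {self.block!r}")
        if self.cv_mode not in ("normal", "reduced"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")
        if self.cv_mode == "reduced" and self.block == "none":
            raise ValueError("reduced CV applies to the blocked ventricle; "
                             "no block side given")


def apply_cv_reduction(tissue_ep: TissueEP, side: str,
                       longitudinal_m_per_s: float = REDUCED_CV_M_PER_S
                       ) -> TissueEP:
    """Reduce longitudinal CV in the affected ventricle, keeping ratios.

    The 4:2:1 off-axis ratio is preserved, so 0.3 m/s longitudinal gives
    (0.3, 0.15, 0.075); the other ventricle is untouched.
    """
    if side == "none":
        return tissue_ep
    label = {"left": Tissue.LV, "right": Tissue.RV}[side]
    v = np.asarray(tissue_ep.velocities[label], float)
    scaled = tuple(v * (longitudinal_m_per_s / v[0]))
    return tissue_ep.with_velocity(label, scaled)


@dataclass
class RunResult:
    scenario: Scenario
    activation: ActivationMap
    vm: VmTraceSet
    ecg_raw: ECGRecording
    ecg: ECGRecording               # filtered
    intervals: IntervalReport
    manifest: dict


class Pipeline:
    """Builds and caches every stage of the virtual-heart pipeline."""

    def __init__(self, heart_config: HeartConfig | None = None,
                 torso_config: TorsoConfig | None = None,
                 branch_config: BranchConfig | None = None,
                 tissue_ep: TissueEP | None = None,
                 ms_params: MSParams | None = None,
                 repol: RepolConfig | None = None,
                 conductivities: ConductivityConfig | None = None,
                 fascicles=None, seed: int = 0,
                 target_pr_ms: float = 200.0):
        self.heart_config = heart_config or HeartConfig()
        self.torso_config = torso_config or TorsoConfig()
        self.branch_config = branch_config or BranchConfig()
        self.tissue_ep = tissue_ep or TissueEP()
        self.ms_params = ms_params or MSParams()
        self.repol = repol or RepolConfig()
        self.conductivities = conductivities or ConductivityConfig()
        self.fascicles = fascicles
        self.seed = int(seed)
        self.target_pr_ms = float(target_pr_ms)

        self._heart: HeartModel | None = None
        self._torso: TorsoModel | None = None
        self._fem: TorsoFEM | None = None
        self._leadfields: LeadFieldSet | None = None
        self._ecg_op: ECGForwardOperator | None = None
        self._system: ConductionSystem | None = None
        self._solver: EikonalSolver | None = None
        self._tau_close: np.ndarray | None = None
        self._ari: np.ndarray | None = None
        self._avn_tuned = False
        self.tuned_avn_cv: float | None = None

    # -- lazily built artifacts -------------------------------------------

    @property
    def heart(self) -> HeartModel:
        if self._heart is None:
            self._heart = build_heart(self.heart_config)
        return self._heart

    @property
    def torso(self) -> TorsoModel:
        if self._torso is None:
            self._torso = build_torso(self.heart, self.torso_config)
        return self._torso

    @property
    def fem(self) -> TorsoFEM:
        if self._fem is None:
            self._fem = TorsoFEM(self.torso, self.conductivities)
        return self._fem

    @property
    def leadfields(self) -> LeadFieldSet:
        if self._leadfields is None:
            lf = compute_lead_fields(self.fem)
            self._leadfields = sample_leadfields_on_heart(
                lf, self.torso, self.heart.mesh)
        return self._leadfields

    @property
    def ecg_operator(self) -> ECGForwardOperator:
        if self._ecg_op is None:
            self._ecg_op = ECGForwardOperator(
                self.leadfields, self.heart.mesh, self.conductivities)
        return self._ecg_op

    @property
    def system(self) -> ConductionSystem:
        if self._system is None:
            tree = grow_tree(self.heart, fascicles=self.fascicles,
                             branch_config=self.branch_config, seed=self.seed)
            tree = tune_terminal_cvs(tree)
            self._system = attach_avn(tree, self.heart)
        return self._system

    @property
    def solver(self) -> EikonalSolver:
        if self._solver is None:
            self._solver = EikonalSolver(self.heart.mesh, self.tissue_ep)
        return self._solver

    def ventricular_mask(self) -> np.ndarray:
        mask = np.zeros(self.heart.mesh.n_nodes, dtype=bool)
        mask[self.heart.mesh.nodes_of(VENTRICULAR)] = True
        return mask

    # -- tuning ------------------------------------------------------------

    def _simulate(self, system: ConductionSystem, tissue_ep: TissueEP,
                  scenario: Scenario):
        if scenario.rhythm == "sinus":
            protocol = StimulusProtocol.sinus(self.heart.san_node,
                                              scenario.baseline_ms)
        else:
            if not scenario.pacing_sources:
                raise ValueError("paced rhythm needs pacing_sources")
            protocol = StimulusProtocol(
                sources=[(int(n), float(t)) for n, t in
                         scenario.pacing_sources], name="paced")
        solver = (self.solver if tissue_ep is self.tissue_ep
                  else EikonalSolver(self.heart.mesh, tissue_ep))
        amap = solve_coupled(self.heart.mesh, system, tissue_ep, protocol,
                             solver=solver)
        vm = reaction_eikonal_vm(amap.at, self.tau_close_field(),
                                 self.ms_params,
                                 duration_ms=scenario.beat_ms)
        ecg_raw = self.ecg_operator(vm.vm, vm.times)
        ecg = filter_ecg(ecg_raw)
        return amap, vm, ecg_raw, ecg

    def tau_close_field(self) -> np.ndarray:
        """Sinus-derived tau_close field (fixed across pathologies)."""
        if self._tau_close is None:
            protocol = StimulusProtocol.sinus(self.heart.san_node)
            amap = solve_coupled(self.heart.mesh, self.system, self.tissue_ep,
                                 protocol, solver=self.solver)
            ari, tc, _ = ventricular_repolarization_fields(
                amap.at, self.ventricular_mask(), self.repol, self.ms_params)
            self._ari, self._tau_close = ari, tc
        return self._tau_close

    def ari_field(self) -> np.ndarray:
        self.tau_close_field()
        return self._ari

    def tune_avn(self) -> float:
        """Tune the AVN conduction velocity to the PR target (sinus)."""
        if self._avn_tuned:
            return self.tuned_avn_cv
        scenario = Scenario(seed=self.seed)

        def evaluate(cv: float) -> float:
            system = self.system.with_avn_cv(cv)
            *_, ecg = self._simulate(system, self.tissue_ep, scenario)
            pr = measure_intervals(ecg).pr_ms
            if pr is None:
                raise RuntimeError("no P wave detected during AVN tuning")
            return pr

        cv, pr = tune_avn_cv(evaluate, self.system.avn.length_mm,
                             self.target_pr_ms,
                             initial_cv=self.system.avn.cv_m_per_s)
        self._system = self.system.with_avn_cv(cv)
        self._avn_tuned = True
        self.tuned_avn_cv = cv
        return cv

    # -- scenario execution -------------------------------------------------

    def run_scenario(self, scenario: Scenario) -> RunResult:
        """Simulate one full beat for the given scenario.

        Sinus-driven scenarios require the AVN to have been tuned; lead
        fields, tree, tuning and the repolarization field are reused.
        """
        if scenario.rhythm == "sinus" and not self._avn_tuned:
            raise RuntimeError("AVN not tuned: call tune_avn() before "
                               "running sinus-driven scenarios")
        system = self.system.with_block(scenario.block)
        tissue_ep = (apply_cv_reduction(self.tissue_ep, scenario.block)
                     if scenario.cv_mode == "reduced" else self.tissue_ep)
        amap, vm, ecg_raw, ecg = self._simulate(system, tissue_ep, scenario)
        intervals = measure_intervals(ecg)
        manifest = self._manifest(scenario)
        return RunResult(scenario=scenario, activation=amap, vm=vm,
                         ecg_raw=ecg_raw, ecg=ecg, intervals=intervals,
                         manifest=manifest)

    def _manifest(self, scenario: Scenario) -> dict:
        cfg = {
            "scenario": asdict(scenario),
            "heart_config": asdict(self.heart_config),
            "torso_config": asdict(self.torso_config),
            "branch_config": asdict(self.branch_config),
            "tissue_ep": {str(int(k)): list(v) for k, v in
                          self.tissue_ep.velocities.items()},
            "ms_params": asdict(self.ms_params),
            "repol": asdict(self.repol),
            "seed": self.seed,
            "tuned_avn_cv_m_per_s": self.tuned_avn_cv,
            "version": __version__,
        }
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        cfg["config_hash"] = digest[:16]
        cfg["tree_stats"] = {
            "n_nodes": int(self.system.tree.n_nodes),
            "n_pmjs": int(len(self.system.tree.pmj_mesh_nodes)),
            "n_cables": int(len(self.system.tree.cable_lengths_mm)),
        }
        return cfg
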