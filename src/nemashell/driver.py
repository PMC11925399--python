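"""Scenario orchestration: pulse trains, single events, regeneration, scans.

A scenario couples a relaxed spheroidal shell, an initial nematic pattern
and a morphogen field.  Global fiber contractions are Gaussian pulses of
active stress; single-event runs freeze the nematic and morphogen fields
(timescale separation), regeneration runs interleave all three dynamics
over a train of pulses and classify the final defect/morphogen state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from nemashell.shell import CellularShell, compute_geometry, graph_distances
from nemashell.synthetic import generate_sphere_shell, init_nematic
from nemashell.mechanics import (
    MechanicsParams,
    MechanicsState,
    elastic_energy,
    force_residual,
    handle_topology,
    relax,
    step_dynamics,
)
from nemashell.nematic import DefectSet, NematicField, detect_defects, step_nematic
from nemashell.morphogen import (
    MorphogenField,
    MorphogenParams,
    gradient_estimate,
    stable_dt,
    step_morphogen_train,
)
from nemashell import strain as strain_mod


# ---------------------------------------------------------------------------
# contraction protocol
# ---------------------------------------------------------------------------


@dataclass
class ContractionProtocol:
    """Gaussian active-stress pulse train.

    ``zeta(t) = zeta_M * sum_k exp(-(t - t_k)^2 / (2 dT^2))`` with pulse
    centers t_k either given explicitly or at k * period.
    """

    zeta_M: float = 0.9
    dT: float = 3.0          # pulse width
    period: float = 20.0     # pulse period for trains
    centers: np.ndarray | None = None

    def __post_init__(self):
        if self.zeta_M < 0:
            raise ValueError("zeta_M must be non-negative")
        if self.centers is None and self.dT >= self.period:
            raise ValueError("pulse width must be below the period")

    def pulse_centers(self, n_pulses: int | None = None) -> np.ndarray:
        if self.centers is not None:
            return np.asarray(self.centers, dtype=float)
        n = 1 if n_pulses is None else n_pulses
        return self.period * (0.5 + np.arange(n))


def contraction_amplitude(t: float, protocol: ContractionProtocol,
                          n_pulses: int | None = None) -> float:
    tk = protocol.pulse_centers(n_pulses)
    return float(protocol.zeta_M *
                 np.exp(-((t - tk) ** 2) / (2 * protocol.dT ** 2)).sum())


# ---------------------------------------------------------------------------
# scenario setup
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    n_cells: int = 200
    mesh_seed: int = 0
    pattern: str = "late_defects"
    pattern_seed: int = 0
    disordered_fraction: float = 1.0 / 3.0
    pair_separation: float = 4.0
    relax_steps: int = 400
    mechanics: MechanicsParams = dc_field(default_factory=MechanicsParams)
    tau_q: float = 3.0
    alpha: float = 10.0
    morphogen: MorphogenParams = dc_field(default_factory=MorphogenParams)

    def __post_init__(self):
        if self.n_cells < 20:
            raise ValueError("n_cells must be >= 20")


@dataclass
class SimulationState:
    mech: MechanicsState
    nem: NematicField
    mor: MorphogenField
    config: ScenarioConfig
    foci: list[int] = dc_field(default_factory=list)

    @property
    def shell(self) -> CellularShell:
        return self.mech.shell

    @property
    def geom(self):
        return self.mech.geom

    def copy(self) -> "SimulationState":
        mech = MechanicsState(self.mech.shell.copy(), self.mech.params,
                              V0=self.mech.V0, time=self.mech.time)
        mech.geom.e1 = self.mech.geom.e1.copy()
        mech.geom.e2 = self.mech.geom.e2.copy()
        return SimulationState(mech, self.nem.copy(), self.mor.copy(),
                               self.config, list(self.foci))


def find_foci(state: SimulationState, merge_distance: int | None = None) -> list[int]:
    """Cells at the centers of the positive-charge actin foci.

    For defect patterns, positive defects are merged within a graph
    distance of ~1.5x the configured pair separation into foci of net
    charge ~ +1; for the fragment pattern the two disordered caps (around
    the +-z poles of the pattern axis) are the foci.
    """
    shell, geom = state.shell, state.geom
    if state.config.pattern == "fragment":
        c = geom.centers - geom.centers.mean(axis=0)
        return [int(np.argmax(c[:, 2])), int(np.argmin(c[:, 2]))]
    if merge_distance is None:
        merge_distance = int(round(1.5 * state.config.pair_separation))
    ds = detect_defects(shell, geom, state.nem)
    pos = [d for d in ds.defects if d.charge > 0.25]
    if not pos:
        return []
    groups: list[list] = []
    for d in sorted(pos, key=lambda d: -d.charge):
        placed = False
        for g in groups:
            dist = graph_distances(shell, [g[0].cell])[d.cell]
            if dist <= merge_distance:
                g.append(d)
                placed = True
                break
        if not placed:
            groups.append([d])
    foci = []
    for g in groups:
        if sum(d.charge for d in g) >= 0.75:
            if len(g) == 1:
                foci.append(int(g[0].cell))
            else:
                # midpoint of a defect pair: minimax graph distance to members
                dists = np.stack([graph_distances(shell, [d.cell]) for d in g])
                foci.append(int(np.argmin(dists.max(axis=0))))
    return foci


def build_scenario(config: ScenarioConfig, relax_tol: float = 2e-3) -> SimulationState:
    """Generate, relax and initialize a full simulation state.

    The morphogen reference areas are the cell areas of the relaxed (t=0)
    state; the morphogen starts at zero.
    """
    shell = generate_sphere_shell(config.n_cells, config.mesh_seed)
    mech = MechanicsState(shell, config.mechanics)
    relax(mech, tol=relax_tol, max_steps=config.relax_steps)
    nem = init_nematic(shell, config.pattern, seed=config.pattern_seed,
                       tau_q=config.tau_q, alpha=config.alpha,
                       pair_separation=config.pair_separation,
                       disordered_fraction=config.disordered_fraction)
    mor = MorphogenField(np.zeros(shell.n_cells), mech.geom.areas.copy(),
                         config.morphogen)
    state = SimulationState(mech, nem, mor, config)
    state.foci = find_foci(state)
    return state


# ---------------------------------------------------------------------------
# single stretching events
# ---------------------------------------------------------------------------


@dataclass
class EventRecord:
    times: np.ndarray               # (F,)
    areas: np.ndarray               # (F, C)
    focus: int
    distances: np.ndarray           # (C,) graph distance from focus
    peak_frame: int
    profile: strain_mod.StrainProfile
    classification: str
    n_t1: int = 0                            # net neighbor exchanges (true T1s)
    n_topo_events: int = 0                   # transient collapse/revert churn
    final_areas: np.ndarray | None = None
    vertex_frames: np.ndarray | None = None  # (F, n_vertices, 3)
    shell: CellularShell | None = None       # connectivity of the run


def _adjacency_pairs(shell: CellularShell) -> set:
    return {frozenset((int(a), int(b))) for a, b in shell.bond_cells if b >= 0}


def _dt_eff(p: MechanicsParams, zeta: float) -> float:
    """Shrink the step during strong pulses (active stiffness adds to the bound)."""
    bound = 0.1 * p.gamma / (p.K * p.A0 + p.Gamma + p.beta / p.A0 + abs(zeta))
    return min(p.dt, bound)


def run_single_event(state: SimulationState, protocol: ContractionProtocol,
                     focus: int | None = None, record_every: int = 10,
                     window_sigmas: float = 4.0, allow_t1: bool = False,
                     relax_tol: float = 5e-2,
                     settle_time: float | None = None) -> EventRecord:
    """Mechanics through one contraction pulse with frozen fields.

    The nematic and morphogen dynamics are frozen (the driver simply does
    not step them).  Per-frame cell areas are recorded; the peak frame and
    the strain-versus-distance profile are computed afterwards.
    """
    st = state.copy()
    if force_residual(st.mech) > relax_tol:
        raise ValueError("single-event runs require a relaxed initial state")
    if focus is None:
        if not st.foci:
            raise ValueError("no focus available; supply one explicitly")
        focus = st.foci[0]
    dists = graph_distances(st.shell, [focus])
    p = st.mech.params
    tc = float(protocol.pulse_centers(1)[0])
    t0 = tc - window_sigmas * protocol.dT
    t1 = tc + window_sigmas * protocol.dT
    if settle_time is None:
        settle_time = 2.0 * protocol.dT
    st.mech.time = t0
    areas0 = st.geom.areas.copy()
    adj0 = _adjacency_pairs(st.shell)
    times = [t0]
    frames = [areas0]
    vframes = [st.shell.vertices.copy()]
    n_t1 = 0
    i = 0
    n_topo = 0
    while st.mech.time < t1:
        zeta = contraction_amplitude(st.mech.time, protocol)
        step_dynamics(st.mech, st.nem, zeta, dt=_dt_eff(p, zeta))
        if allow_t1 and handle_topology(st.mech,
                                        probe_multifold=(i % 20 == 0)):
            n_topo += 1
        i += 1
        if i % record_every == 0:
            times.append(st.mech.time)
            frames.append(st.geom.areas.copy())
            vframes.append(st.shell.vertices.copy())
    # post-pulse settling at zero activity (elastic recovery)
    t_end = st.mech.time + settle_time
    while st.mech.time < t_end:
        step_dynamics(st.mech)
        i += 1
        if allow_t1:
            n_topo += int(handle_topology(st.mech,
                                          probe_multifold=(i % 20 == 0)))
    areas = np.array(frames)
    times = np.array(times)
    peak = strain_mod.find_peak_frame(areas, dists)
    profile = strain_mod.log_area_strain_profile(areas0, areas[peak], dists)
    profile.peak_frame = peak
    cls = strain_mod.classify_event(profile)
    # true T1 count: net neighbor exchanges relative to the initial state
    # (transient bond collapses that revert leave the adjacency unchanged)
    n_t1 = len(adj0.symmetric_difference(_adjacency_pairs(st.shell))) // 2
    if n_t1 > 0:
        import warnings

        warnings.warn(f"{n_t1} cell rearrangement(s) during a stretching "
                      "event", stacklevel=2)
    same_topology = all(v.shape == vframes[0].shape for v in vframes)
    vertex_frames = np.array(vframes) if same_topology else None
    return EventRecord(times, areas, focus, dists, peak, profile, cls,
                       n_t1=n_t1, n_topo_events=n_topo,
                       final_areas=st.geom.areas.copy(),
                       vertex_frames=vertex_frames, shell=st.shell)


def calibrate_zeta(state: SimulationState, protocol: ContractionProtocol,
                   target: float = math.log(2), tol: float = 0.05,
                   zeta_hi: float = 8.0, max_iter: int = 30) -> tuple[float, strain_mod.StrainProfile]:
    """Bisection on the pulse amplitude to match the core log strain.

    The core is the set of cells within graph distance 1 of the +1 focus;
    the achieved value is the mean core log strain at the event peak.
    """
    if target == 0:
        rec = run_single_event(state, replace(protocol, zeta_M=0.0))
        return 0.0, rec.profile

    from nemashell.shell import ShellError

    def core_strain(zm):
        rec = run_single_event(state, replace(protocol, zeta_M=zm))
        return rec.profile.core_value, rec.profile

    lo, f_lo, prof_lo = 0.0, 0.0, None
    hi = None
    unstable = zeta_hi
    zm = min(1.0, zeta_hi)
    while hi is None:
        try:
            val, prof = core_strain(zm)
        except ShellError:
            unstable = zm  # instability onset: search below it
            zm = 0.5 * (lo + zm)
            if (unstable - lo) < 1e-3 * unstable:
                raise ValueError(
                    f"target core strain {target:.3f} unreachable before "
                    f"instability onset at zeta_M~{unstable:.3f} "
                    f"(best {f_lo:.3f} at {lo:.3f})")
            continue
        if val >= target:
            hi = zm
        else:
            lo, f_lo, prof_lo = zm, val, prof
            zm = min(1.5 * zm, 0.5 * (zm + unstable))
            if (unstable - lo) < 1e-3 * unstable or zm >= zeta_hi:
                raise ValueError(
                    f"target core strain {target:.3f} unreachable below "
                    f"zeta_M={min(unstable, zeta_hi):.3f} (best {f_lo:.3f} at {lo:.3f})")
    for _ in range(max_iter):
        zm = 0.5 * (lo + hi)
        val, prof = core_strain(zm)
        if abs(val - target) <= tol:
            return zm, prof
        if val < target:
            lo = zm
        else:
            hi = zm
    return zm, prof


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------


@dataclass
class OutcomeLabel:
    category: str                       # single_organizer/two_organizers/four_half/other
    defects: DefectSet
    peaks: list[int]                    # cells that are morphogen peaks
    organizers: list[int]               # defect cells colocalized with peaks
    n_plus1: int
    n_half: int


def morphogen_peaks(shell: CellularShell, geom, mor: MorphogenField,
                    prominence: float = 2.0) -> list[int]:
    """Local maxima of the 1-ring-smoothed concentration above prominence x mean."""
    phi = mor.concentrations(geom.areas)
    smoothed = np.empty_like(phi)
    for c in range(shell.n_cells):
        ring = np.concatenate([[c], shell.cell_neighbors[c]])
        smoothed[c] = phi[ring].mean()
    mean = smoothed.mean()
    peaks = []
    if mean <= 0:
        return peaks
    for c in range(shell.n_cells):
        if smoothed[c] < prominence * mean:
            continue
        if np.all(smoothed[c] >= smoothed[shell.cell_neighbors[c]]):
            peaks.append(c)
    return peaks


def classify_outcome(shell: CellularShell, geom, nem: NematicField,
                     mor: MorphogenField, coloc_distance: int = 2,
                     pair_merge_distance: int = 2) -> OutcomeLabel:
    """Label the final state by its defect configuration and morphogen peaks.

    A +1 defect (or a +1/2 pair within ``pair_merge_distance`` cells,
    counted as a composite) is an organizer iff a morphogen peak lies
    within graph distance ``coloc_distance``.  ``four_half`` requires
    exactly four +1/2 defects and no organizer.
    """
    ds = detect_defects(shell, geom, nem)
    peaks = morphogen_peaks(shell, geom, mor)
    halves = [d for d in ds.defects if abs(d.charge - 0.5) < 1e-9]
    ones = [d for d in ds.defects if abs(d.charge - 1.0) < 1e-9]

    def near_peak(cell):
        if not peaks:
            return False
        dist = graph_distances(shell, [cell])
        return min(dist[p] for p in peaks) <= coloc_distance

    # composite +1: a +1/2 pair within the merge distance counts as a +1
    # site only when it is colocalized with a morphogen peak (otherwise it
    # remains the ordinary "+1/2 defect pair" configuration)
    used = set()
    composites = []
    for i, a in enumerate(halves):
        if i in used:
            continue
        for j in range(i + 1, len(halves)):
            if j in used:
                continue
            if graph_distances(shell, [a.cell])[halves[j].cell] <= pair_merge_distance \
                    and (near_peak(a.cell) or near_peak(halves[j].cell)):
                composites.append(a.cell)
                used.update((i, j))
                break
    free_halves = [h for i, h in enumerate(halves) if i not in used]
    plus_one_sites = [d.cell for d in ones] + composites

    organizers = [c for c in plus_one_sites if near_peak(c)]

    n_plus1 = len(plus_one_sites)
    n_half = len(free_halves)
    if len(organizers) == 1 and n_plus1 == 1:
        category = "single_organizer"
    elif len(organizers) == 2 and n_plus1 == 2:
        category = "two_organizers"
    elif n_plus1 == 0 and n_half == 4 and len(ds.defects) == 4 and not organizers:
        category = "four_half"
    else:
        category = "other"
    return OutcomeLabel(category, ds, peaks, organizers, n_plus1, n_half)


# ---------------------------------------------------------------------------
# full regeneration runs
# ---------------------------------------------------------------------------


@dataclass
class RegenerationResult:
    outcome: OutcomeLabel
    state: SimulationState
    snapshots: list[dict]
    n_t1: int
    aborted_at: float | None = None  # time of a numerical failure, if any


def run_regeneration(state: SimulationState, protocol: ContractionProtocol,
                     n_pulses: int = 20, snapshot_every: float | None = None,
                     allow_t1: bool = True) -> RegenerationResult:
    """Full coupled dynamics over a train of contraction pulses.

    Interleaves mechanics stepping, morphogen sub-stepping (explicit-Euler
    diffusion stability), nematic alignment with gradient coupling, and
    topology handling; classifies the final state after a terminal
    relaxation.
    """
    from nemashell.shell import ShellError

    st = state.copy()
    p = st.mech.params
    t_end = n_pulses * protocol.period
    snapshots = []
    next_snap = 0.0
    n_t1 = 0
    i_step = 0
    grads = None
    last_good = st.copy()
    aborted_at = None
    while st.mech.time < t_end:
        try:
            zeta = contraction_amplitude(st.mech.time, protocol, n_pulses)
            step_dynamics(st.mech, st.nem, zeta, dt=_dt_eff(p, zeta))
        except ShellError:
            # numerical failure: abort with the last good snapshot
            aborted_at = st.mech.time
            st = last_good
            break
        i_step += 1
        if i_step % 200 == 0:
            last_good = st.copy()
        if allow_t1 and handle_topology(st.mech,
                                        probe_multifold=(i_step % 20 == 0)):
            n_t1 += 1
        # morphogen: sub-step to respect the diffusion bound
        if st.mor.params.r_plus != 0.0 or st.mor.N.max() > 0:
            dt_m = stable_dt(st.shell, st.geom, st.mor.params)
            n_sub = max(1, int(np.ceil(p.dt / max(dt_m, 1e-9))))
            st.mor = step_morphogen_train(st.shell, st.geom, st.mor, p.dt, n_sub)
        # nematic: neighbor alignment + morphogen-gradient coupling
        # (gradients refreshed every few steps; the morphogen is slow)
        if st.nem.alpha != 0.0 and st.mor.N.max() > 0 \
                and (grads is None or i_step % 5 == 0):
            phi = st.mor.concentrations(st.geom.areas)
            grads = gradient_estimate(st.shell, st.geom, phi)
        st.nem = step_nematic(st.shell, st.geom, st.nem, p.dt, grads)
        if snapshot_every is not None and st.mech.time >= next_snap:
            snapshots.append({
                "time": st.mech.time,
                "areas": st.geom.areas.copy(),
                "N": st.mor.N.copy(),
                "q": st.nem.q.copy(),
                "energy": elastic_energy(st.shell, p, st.geom),
            })
            next_snap += snapshot_every
    relax(st.mech, tol=5e-3, max_steps=1000)
    outcome = classify_outcome(st.shell, st.geom, st.nem, st.mor)
    return RegenerationResult(outcome, st, snapshots, n_t1, aborted_at)


# ---------------------------------------------------------------------------
# phase scan
# ---------------------------------------------------------------------------


def phase_scan(eps_th_values, alpha_values, seeds, base_config: ScenarioConfig,
               protocol: ContractionProtocol, n_pulses: int = 20):
    """Outcome table over the (eps_th, alpha) grid; failures are recorded."""
    import pandas as pd

    rows = []
    for eps_th in eps_th_values:
        for alpha in alpha_values:
            for seed in seeds:
                cfg = replace(
                    base_config,
                    pattern_seed=seed,
                    alpha=alpha,
                    morphogen=replace(base_config.morphogen, eps_th=eps_th),
                )
                try:
                    st = build_scenario(cfg)
                    res = run_regeneration(st, protocol, n_pulses)
                    out = res.outcome
                    rows.append(dict(eps_th=eps_th, alpha=alpha, seed=seed,
                                     outcome=out.category, n_plus1=out.n_plus1,
                                     n_half=out.n_half, n_peaks=len(out.peaks),
                                     error=""))
                except Exception as exc:  # per-run failures recorded, scan continues
                    rows.append(dict(eps_th=eps_th, alpha=alpha, seed=seed,
                                     outcome="failed", n_plus1=-1, n_half=-1,
                                     n_peaks=-1, error=str(exc)))
    return pd.DataFrame(rows)
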