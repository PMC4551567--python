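"""Multicompartment retinal ganglion cell model.

Morphology: a spherical soma, an axon hillock/initial segment (S1) that
drops 0.5 μm from the soma, turns through a 90° bend of 5 μm radius and
runs 40 μm horizontally; a 40 μm sodium-channel band (S2) of elevated Na
conductance; and a 1000 μm distal axon (S3).  The axon points nasally
(−x).  Five active currents (Na, delayed-rectifier K, A-type K,
Ca-activated K, Ca) plus leak; gating kinetics of the salamander RGC
lineage.  Extracellular stimulation enters through the potential
difference along the fibre (the activating-function pathway): the axial
current couples V_i = V_m + V_e between neighbouring compartments.

Units: mV, ms, μA (stimulus amplitudes), mS/cm² (channel densities),
μF/cm² (capacitance), Ω·cm (axial resistivity), mM (calcium), μm (space).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K

__all__ = [
    "SEGMENTS",
    "Morphology",
    "ChannelParams",
    "CellState",
    "StimulusPulse",
    "build_morphology",
    "rate_constants",
    "membrane_currents",
    "RGCModel",
    "steady_state",
    "detect_spike",
    "find_threshold",
    "threshold_position_profile",
    "IntegrationError",
    "NoThresholdError",
]

SEGMENTS = ("soma", "S1", "S2", "S3")

S1_VERTICAL = 0.5
S1_BEND_RADIUS = 5.0
S1_HORIZONTAL = 40.0
S1_LENGTH = S1_VERTICAL + math.pi / 2 * S1_BEND_RADIUS + S1_HORIZONTAL  # ≈48.35 μm
S2_LENGTH = 40.0
S3_LENGTH = 1000.0


class IntegrationError(RuntimeError):
    """Numerical failure (NaN/overflow) during membrane integration."""


class NoThresholdError(RuntimeError):
    """No activating amplitude exists below the configured cap."""


@dataclass(frozen=True)
class StimulusPulse:
    """Rectangular monophasic current pulse (negative amplitude = cathodic)."""

    amplitude_ua: float = -1.0
    width_ms: float = 0.4
    onset_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("pulse width must be positive")


@dataclass(frozen=True)
class Morphology:
    """Compartmentalised cell geometry.

    ``positions`` are 3-D compartment centres (μm); ``segment`` indexes into
    :data:`SEGMENTS`.  Areas are in cm² (soma: sphere surface πd²; axonal
    compartments: lateral cylinder surface).
    """

    positions: np.ndarray  # (n, 3) μm
    lengths: np.ndarray  # (n,) μm
    diameters: np.ndarray  # (n,) μm
    segment: np.ndarray  # (n,) int in 0..3
    soma_xyz: tuple[float, float, float]
    axon_direction: tuple[float, float, float]

    @property
    def n_compartments(self) -> int:
        return len(self.lengths)

    @property
    def areas_cm2(self) -> np.ndarray:
        area = math.pi * self.diameters * self.lengths * 1e-8
        soma = self.segment == 0
        area[soma] = math.pi * self.diameters[soma] ** 2 * 1e-8
        return area

    def path_length(self, seg: str) -> float:
        m = self.segment == SEGMENTS.index(seg)
        return float(self.lengths[m].sum())

    def translated(self, soma_xyz) -> "Morphology":
        delta = np.asarray(soma_xyz, dtype=float) - np.asarray(self.soma_xyz, dtype=float)
        return replace(self, positions=self.positions + delta, soma_xyz=tuple(soma_xyz))


def build_morphology(
    soma_xyz=(0.0, 0.0, 0.0),
    axon_direction=(-1.0, 0.0, 0.0),
    soma_diameter: float = 24.0,
    diameters: tuple[float, float, float] = (1.0, 0.9, 1.0),  # S1, S2, S3
    ds: float = 1.0,
    ds_distal: float = 5.0,
    s3_fine_length: float = 100.0,
) -> Morphology:
    """Discretise the standard RGC morphology.

    The axon leaves the bottom (vitread) pole of the soma, runs 0.5 μm
    straight down, bends through a quarter circle of radius 5 μm into the
    horizontal ``axon_direction`` (nasal, −x, by default) and continues
    horizontally through S1, S2 and S3.  Compartments are ≤ ``ds`` long in
    S1/S2 and the proximal ``s3_fine_length`` of S3, and ≤ ``ds_distal`` in
    the distal axon.
    """
    ux = float(np.sign(axon_direction[0]) or -1.0)
    xs, ys, zs = (float(v) for v in soma_xyz)
    rs = soma_diameter / 2.0

    def path_point(s: float) -> tuple[float, float, float]:
        """Point at arc length s along the axon (s=0 at the soma surface)."""
        if s <= S1_VERTICAL:
            return (xs, ys, zs - rs - s)
        s2 = s - S1_VERTICAL
        arc = math.pi / 2 * S1_BEND_RADIUS
        if s2 <= arc:
            th = s2 / S1_BEND_RADIUS
            cx = xs + ux * S1_BEND_RADIUS
            cz = zs - rs - S1_VERTICAL
            return (cx - ux * S1_BEND_RADIUS * math.cos(th), ys,
                    cz - S1_BEND_RADIUS * math.sin(th))
        s3 = s2 - arc
        return (xs + ux * (S1_BEND_RADIUS + s3), ys,
                zs - rs - S1_VERTICAL - S1_BEND_RADIUS)

    pts = [(xs, ys, zs)]
    lens = [soma_diameter]
    diams = [soma_diameter]
    segs = [0]

    bounds = [
        (0.0, S1_LENGTH, 1, diameters[0], ds),
        (S1_LENGTH, S1_LENGTH + S2_LENGTH, 2, diameters[1], ds),
        (S1_LENGTH + S2_LENGTH, S1_LENGTH + S2_LENGTH + min(s3_fine_length, S3_LENGTH),
         3, diameters[2], ds),
        (S1_LENGTH + S2_LENGTH + min(s3_fine_length, S3_LENGTH),
         S1_LENGTH + S2_LENGTH + S3_LENGTH, 3, diameters[2], ds_distal),
    ]
    for s0, s1, seg_id, diam, step in bounds:
        if s1 <= s0:
            continue
        ncomp = max(1, int(math.ceil((s1 - s0) / step)))
        edges = np.linspace(s0, s1, ncomp + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            pts.append(path_point(0.5 * (lo + hi)))
            lens.append(hi - lo)
            diams.append(diam)
            segs.append(seg_id)

    return Morphology(
        positions=np.asarray(pts, dtype=float),
        lengths=np.asarray(lens, dtype=float),
        diameters=np.asarray(diams, dtype=float),
        segment=np.asarray(segs, dtype=np.int8),
        soma_xyz=(xs, ys, zs),
        axon_direction=(ux, 0.0, 0.0),
    )


@dataclass(frozen=True)
class ChannelParams:
    """Per-segment maximal conductances (mS/cm²) and shared constants.

    Conductance tuples are ordered (soma, S1, S2, S3).  The sodium peak sits
    on the S2 band (the high-density sodium-channel band); the printed
    column order of the source table is available via ``literal_na_order``.
    """

    g_na: tuple[float, float, float, float] = (70.0, 100.0, 350.0, 80.0)
    g_kdr: tuple[float, float, float, float] = (18.0, 45.0, 18.0, 18.0)
    g_a: tuple[float, float, float, float] = (54.0, 54.0, 54.0, 0.0)
    g_ca: tuple[float, float, float, float] = (1.5, 1.5, 0.0, 0.0)
    g_kca: tuple[float, float, float, float] = (0.065,) * 4
    g_leak: tuple[float, float, float, float] = (0.005,) * 4
    e_na: float = 35.0
    e_k: float = -75.0
    e_ca: float = 132.0
    cm: float = 1.0  # μF/cm², fixed
    ra: float = 110.0  # Ω·cm axial resistivity
    v_rest: float = -65.0
    ca_rest: float = 1e-4  # mM residual intracellular calcium
    ca_tau: float = 1.5  # ms calcium pool time constant
    alpha_a_printed: bool = False

    @classmethod
    def literal_na_order(cls, **kw) -> "ChannelParams":
        """Sodium row assigned in the literal printed column order."""
        return cls(g_na=(70.0, 350.0, 100.0, 80.0), **kw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ChannelParams":
        data = dict(data)
        for key in ("g_na", "g_kdr", "g_a", "g_ca", "g_kca", "g_leak"):
            if key in data:
                data[key] = tuple(float(v) for v in data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "ChannelParams":
        """Load from a YAML/JSON config mirroring the conductance tables."""
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def per_compartment(self, segment: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name in ("g_na", "g_kdr", "g_a", "g_ca", "g_kca", "g_leak"):
            out[name] = np.asarray(getattr(self, name), dtype=float)[segment]
        return out


@dataclass
class CellState:
    v: np.ndarray  # mV per compartment
    gates: dict[str, np.ndarray]  # m, h, n, a, ha, c in [0, 1]
    ca: np.ndarray  # mM
    time_ms: float = 0.0


GATE_NAMES = ("m", "h", "n", "a", "ha", "c")


def rate_constants(v_mv: float, alpha_a_printed: bool = False) -> dict[str, tuple[float, float]]:
    """(α, β) in ms⁻¹ for each gate at membrane potential ``v_mv``.

    Removable singularities of the α expressions evaluate to their analytic
    limits; all outputs are finite and non-negative.
    """
    v = float(v_mv)
    return {
        "m": (K.alpha_m(v), K.beta_m(v)),
        "h": (K.alpha_h(v), K.beta_h(v)),
        "n": (K.alpha_n(v), K.beta_n(v)),
        "a": (K.alpha_a(v, alpha_a_printed), K.beta_a(v)),
        "ha": (K.alpha_ha(v), K.beta_ha(v)),
        "c": (K.alpha_c(v), K.beta_c(v)),
    }


def gate_steady_state(v_mv: float, alpha_a_printed: bool = False) -> dict[str, float]:
    """x_∞ = α/(α+β) for each gate."""
    out = {}
    for name, (a, b) in rate_constants(v_mv, alpha_a_printed).items():
        out[name] = a / (a + b) if (a + b) > 0 else 0.0
    return out


def membrane_currents(state: CellState, params: ChannelParams,
                      segment: np.ndarray,
                      e_leak: float | np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Ionic current densities (μA/cm²) per compartment; positive = outward."""
    g = params.per_compartment(segment)
    if e_leak is None:
        e_leak = params.v_rest
    v = state.v
    m, h, n, a, ha, c = (state.gates[k] for k in GATE_NAMES)
    sat = (state.ca / 0.001) / (1.0 + state.ca / 0.001)
    i_na = g["g_na"] * m ** 3 * h * (v - params.e_na)
    i_ca = g["g_ca"] * c ** 3 * (v - params.e_ca)
    i_kdr = g["g_kdr"] * n ** 4 * (v - params.e_k)
    i_a = g["g_a"] * a ** 3 * ha * (v - params.e_k)
    i_kca = g["g_kca"] * sat * (v - params.e_k)
    i_leak = g["g_leak"] * (v - e_leak)
    return {"na": i_na, "ca": i_ca, "kdr": i_kdr, "a": i_a, "kca": i_kca,
            "leak": i_leak,
            "total": i_na + i_ca + i_kdr + i_a + i_kca + i_leak}


class RGCModel:
    """A ready-to-integrate cell: morphology + channels + cable couplings.

    The leak reversal is set per compartment so the resting potential sits
    exactly at ``params.v_rest`` (the source model does not state E_l or the
    resting protocol).  Instances are reusable across stimuli; `simulate`
    does not mutate the stored rest state.
    """

    def __init__(self, morphology: Morphology | None = None,
                 params: ChannelParams | None = None):
        self.morphology = morphology if morphology is not None else build_morphology()
        self.params = params if params is not None else ChannelParams()
        self._prepare()

    def _prepare(self) -> None:
        morph, p = self.morphology, self.params
        seg = morph.segment
        area = morph.areas_cm2  # cm²
        g = p.per_compartment(seg)
        # μS conductances: mS/cm² × cm² × 1e3
        self._gbar = {k: v * area * 1e3 for k, v in g.items()}
        self._gca_density = g["g_ca"]
        self._cap = p.cm * area * 1e3  # nF
        # axial conductance (μS) between consecutive compartments
        d = morph.diameters
        ln = morph.lengths
        # units: Ra[Ω·cm] * L[cm] / area[cm²] = Ω; with L,d in μm:
        # R = 4 Ra (L·1e-4) / (π d² 1e-8) = 4 Ra L/(π d²) · 1e4 Ω
        half_res_ohm = 4.0 * p.ra * (ln / 2.0) / (math.pi * d ** 2) * 1e4
        self._gax = 1.0 / (half_res_ohm[:-1] + half_res_ohm[1:]) * 1e6  # S→μS
        # calcium influx factor: mM/ms per μA/cm² of outward I_Ca
        surf_to_vol = np.where(seg == 0, 6.0 / d, 4.0 / d) * 1e4  # 1/cm
        self._ca_factor = 1e-3 * surf_to_vol / (2.0 * K.FARADAY)
        self._el = self._leak_reversal()
        self._rest = self._analytic_rest()
        self._monitor = morph.n_compartments - 1

    def _leak_reversal(self) -> np.ndarray:
        p = self.params
        v = p.v_rest
        x = gate_steady_state(v, p.alpha_a_printed)
        g = p.per_compartment(self.morphology.segment)
        i_ca = g["g_ca"] * x["c"] ** 3 * (v - p.e_ca)  # μA/cm²
        ca_inf = p.ca_rest - p.ca_tau * (1e-3 * np.where(
            self.morphology.segment == 0,
            6.0 / self.morphology.diameters,
            4.0 / self.morphology.diameters) * 1e4 / (2.0 * K.FARADAY)) * i_ca
        ca_inf = np.maximum(ca_inf, p.ca_rest)
        sat = (ca_inf / 0.001) / (1.0 + ca_inf / 0.001)
        i_other = (g["g_na"] * x["m"] ** 3 * x["h"] * (v - p.e_na)
                   + i_ca
                   + g["g_kdr"] * x["n"] ** 4 * (v - p.e_k)
                   + g["g_a"] * x["a"] ** 3 * x["ha"] * (v - p.e_k)
                   + g["g_kca"] * sat * (v - p.e_k))
        self._ca_inf = ca_inf
        return v + i_other / g["g_leak"]

    def _analytic_rest(self) -> CellState:
        p = self.params
        n = self.morphology.n_compartments
        x = gate_steady_state(p.v_rest, p.alpha_a_printed)
        gates = {k: np.full(n, x[k]) for k in GATE_NAMES}
        return CellState(v=np.full(n, p.v_rest), gates=gates, ca=self._ca_inf.copy())

    @property
    def rest_state(self) -> CellState:
        r = self._rest
        return CellState(v=r.v.copy(), gates={k: g.copy() for k, g in r.gates.items()},
                         ca=r.ca.copy(), time_ms=0.0)

    def simulate(
        self,
        ve_mv: np.ndarray,
        pulse: StimulusPulse | None = None,
        t_total_ms: float | None = None,
        dt_ms: float = 0.005,
        state: CellState | None = None,
        record_every: int = 0,
        stim_scale: np.ndarray | None = None,
        detect_window_ms: float = 5.0,
        spike_threshold_mv: float = 0.0,
        stop_on_spike: bool = True,
    ) -> dict:
        """Integrate the cell under an extracellular potential field.

        ``ve_mv`` is the per-compartment extracellular potential for the
        full stimulus amplitude; it is applied multiplied by the rectangular
        pulse envelope (quasi-static fields scale with the instantaneous
        current).  Alternatively ``stim_scale`` supplies an arbitrary
        per-step envelope.  Returns activation flag, spike time at the
        distal monitor compartment, the peak monitor potential, and the
        recorded trace when ``record_every`` > 0.
        """
        morph = self.morphology
        n = morph.n_compartments
        ve = np.ascontiguousarray(np.broadcast_to(np.asarray(ve_mv, dtype=float), (n,)))
        if pulse is None:
            pulse = StimulusPulse()
        if t_total_ms is None:
            t_total_ms = pulse.onset_ms + detect_window_ms + 0.2
        nsteps = int(round(t_total_ms / dt_ms))
        if stim_scale is None:
            t_new = (np.arange(nsteps) + 1) * dt_ms
            stim_scale = ((t_new > pulse.onset_ms)
                          & (t_new <= pulse.onset_ms + pulse.width_ms)).astype(float)
        else:
            stim_scale = np.ascontiguousarray(stim_scale, dtype=float)
            if len(stim_scale) != nsteps:
                raise ValueError("stim_scale length must equal the number of steps")

        st = state if state is not None else self.rest_state
        v = st.v.copy()
        gates = {k: st.gates[k].copy() for k in GATE_NAMES}
        ca = st.ca.copy()

        if record_every > 0:
            nrec = nsteps // record_every + 1
            record = np.empty((nrec, n))
        else:
            record = np.empty((0, n))

        spiked, spike_time, peak = K.simulate_kernel(
            nsteps, dt_ms, v,
            gates["m"], gates["h"], gates["n"], gates["a"], gates["ha"], gates["c"],
            ca,
            self._gbar["g_na"], self._gbar["g_kdr"], self._gbar["g_a"],
            self._gbar["g_ca"], self._gbar["g_kca"], self._gbar["g_leak"],
            self._el, self._gca_density, self._ca_factor,
            self.params.e_na, self.params.e_k, self.params.e_ca,
            self.params.ca_rest, self.params.ca_tau,
            self._cap, self._gax, ve, stim_scale,
            self.params.alpha_a_printed,
            self._monitor, spike_threshold_mv,
            pulse.onset_ms, pulse.onset_ms + detect_window_ms,
            record, max(record_every, 1), stop_on_spike,
        )
        if spiked < 0:
            raise IntegrationError(
                f"non-finite membrane potential at t={spike_time:.3f} ms")
        out = {
            "activated": bool(spiked),
            "spike_time_ms": spike_time if spiked else None,
            "peak_monitor_mv": peak,
            "state": CellState(v=v, gates=gates, ca=ca, time_ms=nsteps * dt_ms),
            "dt_ms": dt_ms,
            "t_ms": None,
            "v_m": None,
        }
        if record_every > 0:
            out["v_m"] = record
            out["t_ms"] = np.arange(record.shape[0]) * record_every * dt_ms
        return out


def steady_state(params: ChannelParams | None = None,
                 morphology: Morphology | None = None,
                 settle_ms: float = 20.0, check_ms: float = 50.0,
                 dt_ms: float = 0.01) -> CellState:
    """Initialise at the analytic rest point and settle the full dynamics.

    Raises if the membrane drifts by more than 1 mV over ``check_ms`` after
    the settling period, or if the cell spikes spontaneously at rest.
    """
    model = RGCModel(morphology, params)
    zero = np.zeros(model.morphology.n_compartments)
    quiet = StimulusPulse(amplitude_ua=0.0, width_ms=1e-3, onset_ms=0.0)
    r1 = model.simulate(zero, pulse=quiet, t_total_ms=settle_ms, dt_ms=dt_ms,
                        stop_on_spike=False)
    if r1["activated"]:
        raise IntegrationError("spontaneous spiking at rest: bad parameterisation")
    st = r1["state"]
    r2 = model.simulate(zero, pulse=quiet, t_total_ms=check_ms, dt_ms=dt_ms,
                        state=st, stop_on_spike=False)
    drift = np.max(np.abs(r2["state"].v - st.v))
    if drift > 1.0:
        raise IntegrationError(f"resting drift {drift:.2f} mV exceeds 1 mV")
    if r2["activated"]:
        raise IntegrationError("spontaneous spiking at rest: bad parameterisation")
    st2 = r2["state"]
    st2.time_ms = settle_ms + check_ms
    return st2


def export_traces(result: dict, path) -> None:
    """Write a recorded simulation (``record_every`` > 0) as long-format
    CSV with columns time_ms, compartment, v_m_mv."""
    if result.get("v_m") is None:
        raise ValueError("simulation was run without trace recording")
    vm = result["v_m"]
    t = result["t_ms"]
    nrec, n = vm.shape
    out = np.column_stack([
        np.repeat(t, n), np.tile(np.arange(n), nrec), vm.ravel()])
    np.savetxt(path, out, delimiter=",", comments="",
               header="time_ms,compartment,v_m_mv",
               fmt=("%.5f", "%d", "%.6f"))


def detect_spike(trace_mv: np.ndarray, t_ms: np.ndarray,
                 threshold_mv: float = 0.0,
                 window_ms: tuple[float, float] | None = None) -> tuple[bool, float | None]:
    """First upward crossing of ``threshold_mv`` in a monitor-voltage trace."""
    v = np.asarray(trace_mv, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    up = (v[:-1] < threshold_mv) & (v[1:] >= threshold_mv)
    idx = np.nonzero(up)[0]
    if window_ms is not None:
        lo, hi = window_ms
        idx = idx[(t[idx + 1] >= lo) & (t[idx + 1] <= hi)]
    if len(idx) == 0:
        return False, None
    return True, float(t[idx[0] + 1])


def find_threshold(
    model: RGCModel,
    ve_unit_mv: np.ndarray,
    pulse_width_ms: float = 0.4,
    tol: float = 0.01,
    amplitude_cap_ua: float = 1000.0,
    dt_ms: float = 0.005,
    start_ua: float = 1.0,
) -> float:
    """Threshold cathodic current (μA, positive magnitude) by bisection.

    ``ve_unit_mv`` is the extracellular potential per compartment for a
    1 μA cathodic drive (the volume conductor is linear, so the potential
    at amplitude I is I × the unit solution).  Bracket expansion is
    followed by bisection to relative tolerance ``tol``; the returned value
    is the smallest activating amplitude found (the upper bracket).  Raises
    :class:`NoThresholdError` if the cap does not activate the cell.
    """
    ve_unit = np.asarray(ve_unit_mv, dtype=float)
    pulse = StimulusPulse(amplitude_ua=-1.0, width_ms=pulse_width_ms)

    def active(amp: float) -> bool:
        return model.simulate(ve_unit * amp, pulse=pulse, dt_ms=dt_ms)["activated"]

    if not np.any(np.abs(np.diff(ve_unit)) > 0):
        raise NoThresholdError("spatially uniform extracellular field cannot activate")

    lo, hi = 0.0, None
    amp = min(start_ua, amplitude_cap_ua)
    while True:
        if active(amp):
            hi = amp
            break
        lo = amp
        if amp >= amplitude_cap_ua:
            raise NoThresholdError(f"no activation up to {amplitude_cap_ua} μA")
        amp = min(amp * 2.0, amplitude_cap_ua)
    while (hi - lo) > tol * hi:
        mid = 0.5 * (lo + hi)
        if active(mid):
            hi = mid
        else:
            lo = mid
    return hi


def threshold_position_profile(
    field_solution,
    offsets_um: np.ndarray,
    soma_depth_um: float = 49.0,
    params: ChannelParams | None = None,
    pulse_width_ms: float = 0.4,
    tol: float = 0.01,
    axon_direction=(-1.0, 0.0, 0.0),
    dt_ms: float = 0.005,
) -> dict:
    """Single-cell threshold versus electrode offset along the axon.

    ``offsets_um`` are electrode positions measured from the soma along the
    axon direction (positive = over the axon).  Equivalently the soma is
    displaced by +offset with the electrode fixed on the axis.  The minimum
    of the profile is expected over the sodium-channel band.
    """
    from .volume_conductor import sample_potential

    sol_unit = field_solution.scaled_to(-1.0)
    params = params or ChannelParams()
    morph0 = build_morphology(soma_xyz=(0.0, 0.0, soma_depth_um),
                              axon_direction=axon_direction)
    model = RGCModel(morph0, params)
    ux = morph0.axon_direction[0]
    thresholds = []
    for off in np.asarray(offsets_um, dtype=float):
        # electrode at +off along the axon <=> soma displaced by -off·axon_dir
        pos = morph0.positions.copy()
        pos[:, 0] -= ux * off
        ve = sample_potential(sol_unit, pos)
        try:
            thr = find_threshold(model, ve, pulse_width_ms=pulse_width_ms,
                                 tol=tol, dt_ms=dt_ms)
        except NoThresholdError:
            thr = np.nan
        thresholds.append(thr)
    thresholds = np.asarray(thresholds)
    finite = np.isfinite(thresholds)
    imin = int(np.nanargmin(thresholds))
    return {
        "offsets_um": np.asarray(offsets_um, dtype=float),
        "threshold_ua": thresholds,
        "min_offset_um": float(np.asarray(offsets_um)[imin]),
        "min_threshold_ua": float(thresholds[imin]),
        "n_no_threshold": int((~finite).sum()),
    }
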