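"""Double-cable myelinated axon model driven by an extracellular field.

The fibre is the published double-cable representation of a mammalian
myelinated axon: explicit nodes of Ranvier carrying fast Na, persistent
Na and slow K conductances, flanked by myelin attachment (MYSA) and
paranodal (FLUT) segments and six internodal (STIN) segments per
internode.  The myelin sheath and the axolemma are separate electrical
layers coupled through the periaxonal space, so the state per
compartment is the pair (axolemma voltage, sheath voltage).

Only the 5.7 um diameter class is shipped (see ``data/mrg_fiber_5p7um.yaml``);
at this diameter the internodal spacing is 0.5 mm, so a 100 mm fibre has
201 nodes and 2201 compartments.

Extracellular coupling follows the activating-function form: the
unit-drive potential sampled at compartment centres enters the cable
equations through axial difference terms, scaled at run time by the
square pulse train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._kernels import run_plan

__all__ = [
    "AxonMorphology", "PulseTrain", "NoActivationError",
    "build_axon", "simulate_axon", "simulate_axon_batch",
    "simulate_axon_recorded", "find_threshold", "fires_one_to_one",
    "NODE", "MYSA", "FLUT", "STIN",
]

NODE, MYSA, FLUT, STIN = 0, 1, 2, 3

#: spike detector: upward threshold crossing at the recording node
SPIKE_THRESHOLD_MV = -20.0
SPIKE_LOCKOUT_MS = 1.0

#: recording node, counted from the distal end (avoids sealed-end artefacts)
RECORD_NODE_FROM_END = 10

DT_DEFAULT_MS = 0.005
DT_MAX_MS = 0.025
FINE_WINDOW_MS = 15.0
DT_COARSE_MS = 0.05
EQUILIBRATION_MS = 300.0


class NoActivationError(RuntimeError):
    """The fibre does not reach 1:1 firing at the configured maximum drive."""


def _load_param_table() -> dict[float, dict]:
    text = (resources.files("snsvta") / "data" / "mrg_fiber_5p7um.yaml").read_text()
    params = yaml.safe_load(text)
    return {float(params["fiber_diameter_um"]): params}


_PARAM_TABLE = _load_param_table()


@dataclass(eq=False)
class AxonMorphology:
    """Compartmentalised fibre geometry plus the per-type parameter table."""

    fibre_diameter_um: float
    total_length_mm: float
    comp_type: np.ndarray        # (ncomp,) int8, NODE/MYSA/FLUT/STIN
    length_um: np.ndarray
    diameter_um: np.ndarray
    x_center_um: np.ndarray      # compartment centres along the fibre, from one end
    node_indices: np.ndarray
    params: dict = field(repr=False, default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return len(self.comp_type)

    @property
    def n_nodes(self) -> int:
        return len(self.node_indices)

    @property
    def cache_key(self):
        return (self.fibre_diameter_um, self.total_length_mm)


def build_axon(fibre_diameter: float = 5.7, total_length_mm: float = 100.0) -> AxonMorphology:
    """Assemble the compartment sequence node-(MYSA FLUT 6xSTIN FLUT MYSA)-node-..."""
    if total_length_mm <= 0:
        raise ValueError("total_length_mm must be positive")
    if fibre_diameter not in _PARAM_TABLE:
        supported = sorted(_PARAM_TABLE)
        raise ValueError(f"unsupported fibre diameter {fibre_diameter} um; "
                         f"supported diameters: {supported}")
    p = _PARAM_TABLE[fibre_diameter]
    c = p["compartments"]
    internode = float(p["internode_length_um"])
    stin_len = (internode - c["node"]["length_um"] - 2 * c["mysa"]["length_um"]
                - 2 * c["flut"]["length_um"]) / c["stin"]["count"]

    n_nodes = int(math.floor(total_length_mm * 1000.0 / internode)) + 1
    seq_types = [MYSA, FLUT] + [STIN] * c["stin"]["count"] + [FLUT, MYSA]
    seq_len = ([c["mysa"]["length_um"], c["flut"]["length_um"]]
               + [stin_len] * c["stin"]["count"]
               + [c["flut"]["length_um"], c["mysa"]["length_um"]])
    seq_diam = ([c["mysa"]["diameter_um"], c["flut"]["diameter_um"]]
                + [c["stin"]["diameter_um"]] * c["stin"]["count"]
                + [c["flut"]["diameter_um"], c["mysa"]["diameter_um"]])

    types, lens, diams = [], [], []
    for k in range(n_nodes):
        types.append(NODE)
        lens.append(c["node"]["length_um"])
        diams.append(c["node"]["diameter_um"])
        if k < n_nodes - 1:
            types.extend(seq_types)
            lens.extend(seq_len)
            diams.extend(seq_diam)

    lens = np.asarray(lens)
    x_end = np.cumsum(lens)
    x_center = x_end - lens / 2.0
    types = np.asarray(types, dtype=np.int8)
    return AxonMorphology(
        fibre_diameter, total_length_mm, types, lens,
        np.asarray(diams, float), x_center,
        np.flatnonzero(types == NODE).astype(np.int64), p,
    )


# ---------------------------------------------------------------------------
# cable parameters (absolute units: nF, uS)
# ---------------------------------------------------------------------------

_CABLE_CACHE: dict = {}


def _cable(morph: AxonMorphology):
    key = morph.cache_key
    if key in _CABLE_CACHE:
        return _CABLE_CACHE[key]
    p = morph.params
    c = p["compartments"]
    D = float(p["fiber_diameter_um"])
    rho_um = float(p["rho_axial_ohm_cm"]) * 1e4         # ohm*um
    nl = int(p["lamellae"])
    xc = float(p["myelin_cm_uf_cm2_per_lamella"]) / (2 * nl)
    xg = float(p["myelin_gm_s_cm2_per_lamella"]) / (2 * nl)

    n = morph.n_compartments
    L = morph.length_um
    d = morph.diameter_um
    ct = morph.comp_type
    a_mem = np.pi * d * L                                # um^2, axolemma
    a_my = np.pi * D * L                                 # um^2, sheath (outer diameter)

    cm = np.empty(n); cx = np.empty(n); gmy = np.empty(n)
    gion_pas = np.zeros(n); src_pas = np.zeros(n)
    w = np.empty(n)                                      # periaxonal width

    type_key = {NODE: "node", MYSA: "mysa", FLUT: "flut", STIN: "stin"}
    for t, keyname in type_key.items():
        sel = ct == t
        spec = c[keyname]
        cm[sel] = spec["cm_uf_cm2"] * a_mem[sel] * 1e-5
        w[sel] = spec["periaxonal_width_um"]
        if t == NODE:
            cx[sel] = float(spec["sheath_c_uf_cm2"]) * a_my[sel] * 1e-5
            gmy[sel] = float(spec["sheath_g_s_cm2"]) * a_my[sel] * 0.01
        else:
            cx[sel] = xc * a_my[sel] * 1e-5
            gmy[sel] = xg * a_my[sel] * 0.01
            gion_pas[sel] = spec["gpas_s_cm2"] * a_mem[sel] * 0.01
            src_pas[sel] = gion_pas[sel] * spec["epas_mv"]

    # axial conductances between successive compartment centres (uS)
    r_half_a = rho_um * (L / 2.0) * 4.0 / (np.pi * d ** 2)          # ohm
    annulus = np.pi * ((d / 2.0 + w) ** 2 - (d / 2.0) ** 2)          # um^2
    r_half_p = rho_um * (L / 2.0) / annulus
    ga = 1e6 / (r_half_a[:-1] + r_half_a[1:])
    gp = 1e6 / (r_half_p[:-1] + r_half_p[1:])

    sga = np.zeros(n); sgp = np.zeros(n)
    sga[:-1] += ga; sga[1:] += ga
    sgp[:-1] += gp; sgp[1:] += gp

    ch = c["node"]["channels"]
    a_node = a_mem[morph.node_indices]
    cable = {
        "cm": cm, "cx": cx, "gmy": gmy, "gion_pas": gion_pas, "src_pas": src_pas,
        "ga": ga, "gp": gp, "sga": sga, "sgp": sgp,
        "gna": ch["gnabar_s_cm2"] * a_node * 0.01,
        "gnap": ch["gnapbar_s_cm2"] * a_node * 0.01,
        "gk": ch["gkbar_s_cm2"] * a_node * 0.01,
        "gl": ch["gl_s_cm2"] * a_node * 0.01,
        "ena": float(ch["ena_mv"]), "ek": float(ch["ek_mv"]), "el": float(ch["el_mv"]),
        "v_rest": float(p["v_rest_mv"]),
    }
    _CABLE_CACHE[key] = cable
    return cable


# ---------------------------------------------------------------------------
# nodal channel kinetics (rates in 1/ms at the model temperature)
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity filled in."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[~small] = x[~small] / (1.0 - np.exp(-x[~small] / y))
    out[small] = y * (1.0 + x[small] / (2.0 * y))
    return out


def _rates(v: np.ndarray, params: dict):
    celsius = float(params["temperature_c"])
    q = {g: spec["q10"] ** ((celsius - spec["t_ref_c"]) / 10.0)
         for g, spec in params["q10_gates"].items()}
    am = q["m"] * 6.57 * _vtrap(v + 20.4, 10.3)
    bm = q["m"] * 0.304 * _vtrap(-(v + 25.7), 9.16)
    ah = q["h"] * 0.34 * _vtrap(-(v + 114.0), 11.0)
    bh = q["h"] * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    ap = q["p"] * 0.0353 * _vtrap(v + 27.0, 10.2)
    bp = q["p"] * 0.000883 * _vtrap(-(v + 34.0), 10.0)
    as_ = q["s"] * 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    bs = q["s"] * 0.03 / (1.0 + np.exp(-(v + 90.0)))
    return (am, bm), (ah, bh), (ap, bp), (as_, bs)


_LUT_VMIN, _LUT_VMAX, _LUT_DV = -250.0, 150.0, 0.05


def _gating_tables(dts: list[float], params: dict):
    """Per-dt exponential-update tables: x <- A(v) x + B(v)."""
    v = np.arange(_LUT_VMIN, _LUT_VMAX + _LUT_DV / 2, _LUT_DV)
    nv = len(v)
    tabA = np.empty((len(dts), 4, nv))
    tabB = np.empty((len(dts), 4, nv))
    pairs = _rates(v, params)
    for gi, (a, b) in enumerate(pairs):
        tau = 1.0 / (a + b)
        xinf = a * tau
        for ti, dt in enumerate(dts):
            A = np.exp(-dt / tau)
            tabA[ti, gi] = A
            tabB[ti, gi] = xinf * (1.0 - A)
    return tabA, tabB


def _steady_gates(v: float, params: dict, n_nodes: int, nb: int):
    pairs = _rates(np.array([v]), params)
    out = []
    for a, b in pairs:
        out.append(np.full((n_nodes, nb), float(a[0] / (a[0] + b[0]))))
    return out


# ---------------------------------------------------------------------------
# pulse train and integration plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrain:
    """Monophasic square pulse train scaling the unit-drive field."""

    frequency_hz: float = 14.0
    amplitude_scale: float = 1.0
    pulse_width_ms: float = 0.21
    duration_ms: float = 1000.0

    def __post_init__(self):
        if self.frequency_hz <= 0 or self.pulse_width_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("pulse train timing values must be positive")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")
        if self.pulse_width_ms >= self.period_ms:
            raise ValueError("pulse width must be shorter than the period")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def onset_times_ms(self) -> np.ndarray:
        n = int(np.ceil(self.duration_ms / self.period_ms - 1e-9))
        return np.arange(n) * self.period_ms

    def n_pulses(self) -> int:
        return len(self.onset_times_ms)


def _build_plan(train: PulseTrain, dt_fine: float, dt_coarse: float, window_ms: float):
    """Segment list (nsteps, dt, table, pulse?): fine windows after each onset,
    coarse integration through the quiet gaps."""
    onsets = train.onset_times_ms
    segs = []
    t = 0.0

    def add_gap(t0, t1):
        gap = t1 - t0
        if gap <= 1e-12:
            return
        ns = max(1, int(round(gap / dt_coarse)))
        segs.append((ns, gap / ns, 1, False))

    for j, o in enumerate(onsets):
        add_gap(t, o)
        end = min(o + window_ms, train.duration_ms)
        if j + 1 < len(onsets):
            end = min(end, onsets[j + 1])
        ns = max(1, int(round((end - o) / dt_fine)))
        segs.append((ns, (end - o) / ns, 0, True))
        t = end
    add_gap(t, train.duration_ms)

    seg_nsteps = np.array([s[0] for s in segs], dtype=np.int64)
    seg_dt = np.array([s[1] for s in segs])
    seg_table = np.array([s[2] for s in segs], dtype=np.int64)
    seg_pulse = np.array([s[3] for s in segs])
    return seg_nsteps, seg_dt, seg_table, seg_pulse


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

_REST_CACHE: dict = {}


def _rest_state(morph: AxonMorphology):
    """Equilibrated membrane state (no drive), cached per morphology."""
    key = morph.cache_key
    if key in _REST_CACHE:
        return _REST_CACHE[key]
    cab = _cable(morph)
    n = morph.n_compartments
    v0 = cab["v_rest"]
    Vm = np.full((n, 1), v0)
    Vx = np.zeros((n, 1))
    m, h, p, s = _steady_gates(v0, morph.params, morph.n_nodes, 1)
    dt = DT_MAX_MS
    tabA, tabB = _gating_tables([dt, dt], morph.params)
    ns = int(round(EQUILIBRATION_MS / dt))
    _run_kernel(morph, cab, np.zeros((n, 1)), np.zeros((n, 1)),
                np.array([ns]), np.array([dt]), np.array([0]), np.array([False]),
                0.0, 0.0, tabA, tabB, Vm, Vx, m, h, p, s)
    state = (Vm[:, 0].copy(), Vx[:, 0].copy(),
             m[:, 0].copy(), h[:, 0].copy(), p[:, 0].copy(), s[:, 0].copy())
    _REST_CACHE[key] = state
    return state


def _run_kernel(morph, cab, ave1, ave2, seg_nsteps, seg_dt, seg_table, seg_pulse,
                pulse_width, scale, tabA, tabB, Vm, Vx, m, h, p, s,
                probe_idx=None, record=False, n_steps_total=0):
    nb = Vm.shape[1]
    max_spk = 256
    spike_times = np.zeros((nb, max_spk))
    spike_counts = np.zeros(nb, dtype=np.int64)
    rec = int(morph.node_indices[-(RECORD_NODE_FROM_END + 1)])
    if probe_idx is None:
        probe_idx = np.zeros(0, dtype=np.int64)
    probe_vm = np.zeros((n_steps_total if record else 1, max(len(probe_idx), 1)))
    probe_t = np.zeros(n_steps_total if record else 1)
    run_plan(
        cab["cm"], cab["cx"], cab["gmy"], cab["gion_pas"], cab["src_pas"],
        cab["ga"], cab["gp"], cab["sga"], cab["sgp"],
        morph.node_indices, cab["gna"], cab["gnap"], cab["gk"], cab["gl"],
        cab["ena"], cab["ek"], cab["el"],
        ave1, ave2,
        seg_nsteps, seg_dt, seg_table, seg_pulse,
        pulse_width, scale, 0.0,
        _LUT_VMIN, _LUT_DV, tabA, tabB,
        Vm, Vx, m, h, p, s,
        rec, SPIKE_THRESHOLD_MV, SPIKE_LOCKOUT_MS, spike_times, spike_counts,
        probe_idx, probe_vm, probe_t, record,
    )
    return spike_times, spike_counts, probe_vm, probe_t


def _axial_drive(morph: AxonMorphology, unit_potentials_v: np.ndarray):
    """Unit-field axial source terms for layer 1 and layer 2 (nA per unit scale)."""
    cab = _cable(morph)
    ve = np.atleast_2d(np.asarray(unit_potentials_v, float)) * 1000.0   # -> mV
    if ve.shape[1] != morph.n_compartments:
        raise ValueError(f"need one extracellular sample per compartment "
                         f"({morph.n_compartments}), got {ve.shape[1]}")
    dve = np.diff(ve, axis=1)                       # (nb, ncomp-1)
    ga, gp = cab["ga"], cab["gp"]
    nb = ve.shape[0]
    n = morph.n_compartments
    ave1 = np.zeros((n, nb))
    ave2 = np.zeros((n, nb))
    ave1[:-1] += (ga * dve).T
    ave1[1:] -= (ga * dve).T
    ave2[:-1] += ((ga + gp) * dve).T
    ave2[1:] -= ((ga + gp) * dve).T
    return ave1, ave2


def _simulate(morph, unit_potentials, train, dt, probes=None):
    if not (0.0 < dt <= DT_MAX_MS):
        raise ValueError(f"dt must be in (0, {DT_MAX_MS}] ms, got {dt}")
    cab = _cable(morph)
    ave1, ave2 = _axial_drive(morph, unit_potentials)
    nb = ave1.shape[1]
    rest = _rest_state(morph)
    Vm = np.tile(rest[0][:, None], (1, nb))
    Vx = np.tile(rest[1][:, None], (1, nb))
    m = np.tile(rest[2][:, None], (1, nb))
    h = np.tile(rest[3][:, None], (1, nb))
    p = np.tile(rest[4][:, None], (1, nb))
    s = np.tile(rest[5][:, None], (1, nb))

    plan = _build_plan(train, dt, DT_COARSE_MS, FINE_WINDOW_MS)
    seg_nsteps, seg_dt, seg_table, seg_pulse = plan
    tabA, tabB = _gating_tables([dt, DT_COARSE_MS], morph.params)
    record = probes is not None
    n_total = int(seg_nsteps.sum())
    probe_idx = None
    if record:
        probe_idx = np.asarray([int(morph.node_indices[q]) for q in probes], dtype=np.int64)
    spk, cnt, pvm, pt = _run_kernel(
        morph, cab, ave1, ave2, seg_nsteps, seg_dt, seg_table, seg_pulse,
        train.pulse_width_ms, train.amplitude_scale, tabA, tabB,
        Vm, Vx, m, h, p, s, probe_idx, record, n_total)
    spikes = [np.sort(spk[b, :cnt[b]]) for b in range(nb)]
    if record:
        return spikes, pt, pvm
    return spikes


def simulate_axon(morph: AxonMorphology, unit_potentials_v: np.ndarray,
                  train: PulseTrain, dt: float = DT_DEFAULT_MS) -> np.ndarray:
    """Integrate one fibre; return sorted spike times (ms) at the recording node.

    ``unit_potentials_v`` is the extracellular potential (volts) of the
    unit-drive field at each compartment centre; at time t the applied
    potential is ``unit * amplitude_scale * pulse(t)``.
    """
    return _simulate(morph, np.atleast_2d(unit_potentials_v), train, dt)[0]


def simulate_axon_batch(morph: AxonMorphology, unit_potentials_v: np.ndarray,
                        train: PulseTrain, dt: float = DT_DEFAULT_MS) -> list[np.ndarray]:
    """Integrate many fibres sharing one morphology/pulse train in one kernel call."""
    return _simulate(morph, unit_potentials_v, train, dt)


def simulate_axon_recorded(morph: AxonMorphology, unit_potentials_v: np.ndarray,
                           train: PulseTrain, probe_nodes: list[int],
                           dt: float = DT_DEFAULT_MS):
    """Like :func:`simulate_axon` but also records Vm at the given node numbers.

    Returns (spike_times, t_trace_ms, vm_trace (nsteps, nprobes))."""
    spikes, pt, pvm = _simulate(morph, np.atleast_2d(unit_potentials_v), train,
                                dt, probes=probe_nodes)
    return spikes[0], pt, pvm


def fires_one_to_one(spike_times: np.ndarray, train: PulseTrain) -> bool:
    """True iff every pulse onset is followed by exactly one spike before the next."""
    spikes = np.asarray(spike_times, float)
    onsets = train.onset_times_ms
    edges = np.append(onsets, train.duration_ms)
    if len(spikes) != len(onsets):
        return False
    for k in range(len(onsets)):
        n = int(np.count_nonzero((spikes >= edges[k]) & (spikes < edges[k + 1])))
        if n != 1:
            return False
    return True


def find_threshold(morph: AxonMorphology, unit_potentials_v: np.ndarray,
                   train: PulseTrain, tol: float = 0.05,
                   max_scale: float = 64.0, dt: float = DT_DEFAULT_MS) -> float:
    """Smallest amplitude scale giving 1:1 firing, by bracketing + bisection.

    The returned value activates; ``value - tol`` does not.  Raises
    :class:`NoActivationError` when even ``max_scale`` fails (signalled
    distinctly from invalid-input errors).
    """
    unit = np.atleast_2d(np.asarray(unit_potentials_v, float))
    if not np.any(unit != 0.0):
        raise NoActivationError("extracellular potentials are zero everywhere")

    def fires(scale: float) -> bool:
        tr = PulseTrain(train.frequency_hz, scale, train.pulse_width_ms, train.duration_ms)
        return fires_one_to_one(_simulate(morph, unit, tr, dt)[0], tr)

    # bracket upward from a small drive: very strong fields can block (depolarising
    # inactivation), so the search targets the lowest 1:1 amplitude
    lo, hi = 0.0, max(4.0 * tol, 0.05)
    while not fires(hi):
        lo = hi
        hi *= 2.0
        if hi > max_scale:
            raise NoActivationError(f"no 1:1 activation up to scale {max_scale}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
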