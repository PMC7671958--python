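"""Network specification: compartments, synapses, couplings, builders.

The full model has four cells — regular-spiking (RS), fast-spiking (FS),
slow-inhibitory (SI) and intrinsically-bursting (IB) — with the IB cell
split into soma, axon, apical dendrite (``IB_da``) and basal dendrite
(``IB_db``) compartments joined by electrical coupling.  Reduced
configurations successively replace parts of the network by external
pulsatile drives:

``full4``
    the four-cell network; optionally driven by a pulse train onto RS.
``fs_si_ib``
    RS removed; the drive projects straight onto FS and SI with the
    former RS->FS / RS->SI synaptic kinetics.
``fs_si_2inputs``
    IB also removed; a second, slower drive (input-2) projects onto FS
    and SI with the former IB->FS / IB->SI kinetics.
``si_only``
    single SI cell (with an inhibitory autapse); input-1 excitatory,
    input-2 inhibitory with the former FS->SI kinetics.
``multiplex3``
    three copies of ``si_only`` plus an output RS cell, the three
    input-2 drives being phase-shifted copies of one another
    (time-division multiplexing demonstration).

All constants live in ``configs/parietal_beta1.yaml``.  Named variants
(``fast_h``, ``weak_fs_si``, ``strong_input1``) apply the parameter
modifications used in specific runs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from pulsegate.kinetics import GatingKinetics

__all__ = [
    "CompartmentParams",
    "ChemicalSynapse",
    "ElectricalCoupling",
    "NetworkSpec",
    "load_parameters",
    "build_network",
    "CONFIG_IDS",
]

CONFIG_IDS = ("full4", "fs_si_ib", "fs_si_2inputs", "si_only", "multiplex3")

# currents carried by each cell type; absent currents have conductance 0
_CURRENTS = ("L", "Na", "K", "AR", "KM", "CaH")


@dataclass
class CompartmentParams:
    """Membrane constants of one point compartment."""

    name: str
    C: float
    J: float
    g: dict[str, float]  # conductance per current, keys in _CURRENTS
    E: dict[str, float]  # reversal potential per current
    kinetics: GatingKinetics = field(default_factory=GatingKinetics)

    def __post_init__(self) -> None:
        for cur, val in self.g.items():
            if cur not in _CURRENTS:
                raise KeyError(f"unknown current {cur!r}")
            if val < 0:
                raise ValueError(f"negative conductance for {cur}")
        for cur in _CURRENTS:
            self.g.setdefault(cur, 0.0)
            self.E.setdefault(cur, 0.0)

    @property
    def gate_kinds(self) -> list[str]:
        """Gating variables this compartment actually carries."""
        kinds = []
        if self.g["K"] > 0:
            kinds.append("m_K")
        if self.g["Na"] > 0:
            kinds.append("h_Na")
        if self.g["AR"] > 0:
            kinds.append("m_AR")
        if self.g["KM"] > 0:
            kinds.append("m_KM")
        if self.g["CaH"] > 0:
            kinds.append("m_CaH")
        return kinds


@dataclass
class ChemicalSynapse:
    """First-order chemical synapse (source may be an external drive)."""

    source: str  # compartment name, or "drive:<name>"
    target: str
    g: float
    V0: float  # reversal, mV
    tau_d: float  # decay, ms
    tau_r: float  # rise, ms
    label: str = ""

    def __post_init__(self) -> None:
        if self.tau_d <= 0 or self.tau_r <= 0:
            raise ValueError("synaptic time constants must be positive")

    @property
    def is_external(self) -> bool:
        return self.source.startswith("drive:")


@dataclass
class ElectricalCoupling:
    a: str
    b: str
    g: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("coupling conductance must be non-negative")


@dataclass
class NetworkSpec:
    """A concrete network: compartments, couplings, synapses, drives."""

    config_id: str
    compartments: dict[str, CompartmentParams]
    synapses: list[ChemicalSynapse]
    couplings: list[ElectricalCoupling]
    drives: list[str]  # names of external drives, in attachment order
    params_version: int = 1
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = set(self.compartments)
        for syn in self.synapses:
            if syn.target not in names:
                raise ValueError(f"synapse target {syn.target!r} undeclared")
            if not syn.is_external and syn.source not in names:
                raise ValueError(f"synapse source {syn.source!r} undeclared")
            if syn.is_external and syn.source[6:] not in self.drives:
                raise ValueError(f"drive {syn.source!r} undeclared")
        for cpl in self.couplings:
            if cpl.a not in names or cpl.b not in names:
                raise ValueError("coupling endpoint undeclared")

    def slow_variables(self, cell_prefix: str = "IB",
                       threshold: float = 10.0) -> list[str]:
        """Names of slow state variables associated with a cell.

        Gating variables with tau > threshold ms throughout the
        subthreshold range, plus synaptic states with tau_d > threshold
        whose target (or source, for the intra-cell synapse) belongs to
        the cell.
        """
        out = []
        for name, comp in self.compartments.items():
            if not name.startswith(cell_prefix):
                continue
            for kind in comp.gate_kinds:
                if comp.kinetics.is_slow(kind, threshold=threshold):
                    out.append(f"{name}.{kind}")
        for syn in self.synapses:
            if syn.target.startswith(cell_prefix) and syn.tau_d > threshold:
                out.append(f"syn:{syn.label}")
        return out


# --------------------------------------------------------------------------
# parameter loading


def load_parameters() -> dict:
    """Load the shipped parameter file (version, cells, synapses...)."""
    ref = resources.files("pulsegate") / "configs" / "parietal_beta1.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _compartment(name: str, raw: dict) -> CompartmentParams:
    g = {c: float(raw.get(f"g_{c}", 0.0)) for c in _CURRENTS}
    E = {c: float(raw.get(f"E_{c}", 0.0)) for c in _CURRENTS}
    kin = GatingKinetics(raw.get("tau_scale") or {})
    return CompartmentParams(name, float(raw["C"]), float(raw["J"]), g, E, kin)


def _synapse(src: str, tgt: str, g: float, kin: dict,
             label: str) -> ChemicalSynapse:
    return ChemicalSynapse(src, tgt, g, float(kin["V0"]),
                           float(kin["tau_d"]), float(kin["tau_r"]), label)


def build_network(config_id: str,
                  variants: tuple[str, ...] = ()) -> NetworkSpec:
    """Construct the requested network topology with shipped parameters.

    ``variants`` names parameter modifications defined in the config
    file (e.g. ``fast_h`` for the faster dendritic h-current kinetics,
    ``weak_fs_si``, ``strong_input1``).
    """
    if config_id not in CONFIG_IDS:
        raise ValueError(f"unknown config_id {config_id!r}; "
                         f"expected one of {CONFIG_IDS}")
    prm = copy.deepcopy(load_parameters())
    for var in variants:
        if var not in prm.get("variants", {}):
            raise KeyError(f"unknown variant {var!r}")
        _apply_variant(prm, prm["variants"][var])

    cells = prm["cells"]
    syn_g = prm["synapse_conductances"]
    kin = prm["synapse_kinetics"]

    def cp(name, cellkey=None):
        return _compartment(name, cells[cellkey or name])

    def syn(label, src, tgt, kin_name, g_key=None):
        return _synapse(src, tgt, float(syn_g[g_key or label]),
                        kin[kin_name], label)

    ib_comps = {n: cp(n) for n in ("IB_soma", "IB_a", "IB_da", "IB_db")}
    ib_couplings = [
        ElectricalCoupling("IB_soma", "IB_a", prm["couplings"]["soma_axon"]),
        ElectricalCoupling("IB_soma", "IB_da", prm["couplings"]["soma_da"]),
        ElectricalCoupling("IB_soma", "IB_db", prm["couplings"]["soma_db"]),
    ]
    ib_internal_syn = [syn("IB_a->IB_db", "IB_a", "IB_db", "a_db",
                           g_key="a_db")]
    ib_out = lambda tgt: syn(f"IB->{tgt}", "IB_a", tgt, f"IB_{tgt}",
                             g_key=f"IB_{tgt}")
    si_ib = syn("SI->IB", "SI", "IB_da", "SI_IB", g_key="SI_IB")

    if config_id == "full4":
        comps = {"RS": cp("RS"), "FS": cp("FS"), "SI": cp("SI"), **ib_comps}
        synapses = [
            syn("RS->FS", "RS", "FS", "RS_FS", g_key="RS_FS"),
            syn("RS->SI", "RS", "SI", "RS_SI", g_key="RS_SI"),
            syn("FS->RS", "FS", "RS", "FS_RS", g_key="FS_RS"),
            syn("FS->SI", "FS", "SI", "FS_SI", g_key="FS_SI"),
            syn("FS->FS", "FS", "FS", "FS_FS", g_key="FS_FS"),
            syn("SI->SI", "SI", "SI", "SI_SI", g_key="SI_SI"),
            si_ib, ib_out("FS"), ib_out("SI"), *ib_internal_syn,
            # optional pulsatile drive onto RS (input-1 relay target)
            _synapse("drive:input1", "RS", float(syn_g["input1_RS"]),
                     kin["RS_FS"], "input1->RS"),
        ]
        return NetworkSpec(config_id, comps, synapses, ib_couplings,
                           ["input1"], prm["version"], variants)

    if config_id == "fs_si_ib":
        comps = {"FS": cp("FS"), "SI": cp("SI"), **ib_comps}
        synapses = [
            _synapse("drive:input1", "FS", float(syn_g["RS_FS"]),
                     kin["RS_FS"], "input1->FS"),
            _synapse("drive:input1", "SI", float(syn_g["RS_SI"]),
                     kin["RS_SI"], "input1->SI"),
            syn("FS->SI", "FS", "SI", "FS_SI", g_key="FS_SI"),
            syn("FS->FS", "FS", "FS", "FS_FS", g_key="FS_FS"),
            syn("SI->SI", "SI", "SI", "SI_SI", g_key="SI_SI"),
            si_ib, ib_out("FS"), ib_out("SI"), *ib_internal_syn,
        ]
        return NetworkSpec(config_id, comps, synapses, ib_couplings,
                           ["input1"], prm["version"], variants)

    if config_id == "fs_si_2inputs":
        comps = {"FS": cp("FS"), "SI": cp("SI")}
        synapses = [
            _synapse("drive:input1", "FS", float(syn_g["RS_FS"]),
                     kin["RS_FS"], "input1->FS"),
            _synapse("drive:input1", "SI", float(syn_g["RS_SI"]),
                     kin["RS_SI"], "input1->SI"),
            _synapse("drive:input2", "FS", float(syn_g["IB_FS"]),
                     kin["IB_FS"], "input2->FS"),
            _synapse("drive:input2", "SI", float(syn_g["IB_SI"]),
                     kin["IB_SI"], "input2->SI"),
            syn("FS->SI", "FS", "SI", "FS_SI", g_key="FS_SI"),
            syn("FS->FS", "FS", "FS", "FS_FS", g_key="FS_FS"),
            syn("SI->SI", "SI", "SI", "SI_SI", g_key="SI_SI"),
        ]
        return NetworkSpec(config_id, comps, synapses, [],
                           ["input1", "input2"], prm["version"], variants)

    if config_id == "si_only":
        comps = {"SI": cp("SI")}
        synapses = [
            _synapse("drive:input1", "SI", float(syn_g["RS_SI"]),
                     kin["RS_SI"], "input1->SI"),
            # input-2 is inhibitory here, with the FS->SI kinetics
            _synapse("drive:input2", "SI", float(syn_g["input2_SI_solo"]),
                     kin["FS_SI"], "input2->SI"),
            syn("SI->SI", "SI", "SI", "SI_SI_solo", g_key="SI_SI_solo"),
        ]
        return NetworkSpec(config_id, comps, synapses, [],
                           ["input1", "input2"], prm["version"], variants)

    # multiplex3: three si_only copies feeding one output RS cell
    comps = {"RS_out": cp("RS_out")}
    synapses = []
    drives = []
    for i in (1, 2, 3):
        si = f"SI{i}"
        comps[si] = cp(si, "SI")
        d1, d2 = f"input1_{i}", f"input2_{i}"
        drives += [d1, d2]
        synapses += [
            _synapse(f"drive:{d1}", si, float(syn_g["RS_SI"]),
                     kin["RS_SI"], f"{d1}->{si}"),
            _synapse(f"drive:{d2}", si, float(syn_g["input2_SI_solo"]),
                     kin["FS_SI"], f"{d2}->{si}"),
            _synapse(si, si, float(syn_g["SI_SI_solo"]), kin["SI_SI_solo"],
                     f"{si}->{si}"),
            _synapse(si, "RS_out", float(syn_g["SI_RSout"]),
                     kin["SI_RSout"], f"{si}->RS_out"),
        ]
    return NetworkSpec("multiplex3", comps, synapses, [], drives,
                       prm["version"], variants)


def _apply_variant(prm: dict, changes: dict) -> None:
    """Apply a variant's multiplicative/absolute overrides in place."""
    for path, value in changes.items():
        keys = path.split(".")
        node = prm
        for k in keys[:-1]:
            node = node[k]
        leaf = keys[-1]
        if isinstance(value, str) and value.startswith("*"):
            node[leaf] = float(node.get(leaf, 1.0)) * float(value[1:])
        else:
            node[leaf] = value
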