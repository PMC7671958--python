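# Parameter set for the parietal beta1 network and its reductions.
#
# changelog:
#   v1  Reconstruction of the published parent period-concatenation model
#       (single cell per type).  Kinetics are Traub-lineage forms (see
#       kinetics.py); per-variable tau scales express the faster axonal
#       M-current and each cell's h-current recovery speed.  Constants
#       were calibrated so the network reproduces the documented
#       behaviours: the SI cell fires in phase with a 40 Hz drive at the
#       input-2 rate with an effective ~16 ms post-input-2 inhibition
#       window and a two-cycle refractory period; the FS-SI-IB network
#       3:7 mode-locks to a 40 Hz drive (mean IB burst rate ~17.1 Hz)
#       with interburst intervals in the mid-50s to low-60s ms and 2-4
#       spikes per burst; the full network oscillates at ~15 Hz.
#
# units: C uF/cm^2, conductances mS/cm^2, potentials mV, times ms.
# sign convention: the membrane equation subtracts J, so J < 0 is a
# depolarising background drive.  Background drives are set so that the
# excitable cells rest at the stated operating points (FS -67, SI -62,
# IB soma/axon -68 mV) and the IB dendrites have no subthreshold rest
# once their M-current has decayed (the drift that paces bursting).

version: 1

cells:
  RS:
    C: 0.9
    J: -1.0
    g_L: 1.0
    E_L: -70.0
    g_Na: 200.0
    E_Na: 50.0
    g_K: 20.0
    E_K: -95.0
    g_AR: 25.0
    E_AR: -35.0
    tau_scale: {m_AR: 0.05}
  RS_out:
    C: 0.9
    J: 16.6103
    g_L: 1.0
    E_L: -70.0
    g_Na: 200.0
    E_Na: 50.0
    g_K: 20.0
    E_K: -95.0
    g_AR: 25.0
    E_AR: -35.0
    tau_scale: {m_AR: 0.05}
  FS:
    C: 0.9
    J: 2.8158
    g_L: 1.0
    E_L: -65.0
    g_Na: 200.0
    E_Na: 50.0
    g_K: 20.0
    E_K: -95.0
  SI:
    C: 0.9
    J: 9.6826
    g_L: 2.0
    E_L: -65.0
    g_Na: 200.0
    E_Na: 50.0
    g_K: 10.0
    E_K: -95.0
    g_AR: 50.0
    E_AR: -35.0
    tau_scale: {m_AR: 0.05}
  IB_soma:
    C: 0.9
    J: -3.6033
    g_L: 2.0
    E_L: -70.0
    g_Na: 125.0
    E_Na: 50.0
    g_K: 10.0
    E_K: -95.0
  IB_a:
    C: 0.9
    J: -0.7319
    g_L: 1.0
    E_L: -70.0
    g_Na: 400.0
    E_Na: 50.0
    g_K: 40.0
    E_K: -95.0
    g_KM: 1.5
    E_KM: -95.0
    tau_scale: {m_KM: 0.8}
  IB_da:
    C: 0.9
    J: -45.6177
    g_L: 2.0
    E_L: -70.0
    g_Na: 125.0
    E_Na: 50.0
    g_K: 10.0
    E_K: -95.0
    g_AR: 40.0
    E_AR: -35.0
    g_KM: 50.0
    E_KM: -95.0
    g_CaH: 4.0
    E_CaH: 125.0
    tau_scale: {m_AR: 0.10, m_KM: 0.84}
  IB_db:
    C: 0.9
    J: -45.6177
    g_L: 2.0
    E_L: -70.0
    g_Na: 125.0
    E_Na: 50.0
    g_K: 10.0
    E_K: -95.0
    g_AR: 40.0
    E_AR: -35.0
    g_KM: 50.0
    E_KM: -95.0
    g_CaH: 4.0
    E_CaH: 125.0
    tau_scale: {m_AR: 0.10, m_KM: 0.84}

couplings:
  soma_axon: 2.0
  soma_da: 1.0
  soma_db: 1.0

synapse_kinetics:
  RS_FS: {V0: 0.0, tau_r: 0.25, tau_d: 1.0}
  RS_SI: {V0: 0.0, tau_r: 0.25, tau_d: 1.0}
  FS_RS: {V0: -80.0, tau_r: 0.5, tau_d: 8.0}
  FS_SI: {V0: -80.0, tau_r: 0.5, tau_d: 8.0}
  FS_FS: {V0: -80.0, tau_r: 0.5, tau_d: 5.0}
  SI_IB: {V0: -80.0, tau_r: 0.5, tau_d: 20.0}
  SI_SI: {V0: -80.0, tau_r: 0.5, tau_d: 10.0}
  # stand-alone SI configurations: the autapse also stands in for the
  # removed per-pulse FS inhibition, hence stronger and slower
  SI_SI_solo: {V0: -80.0, tau_r: 0.5, tau_d: 14.0}
  IB_FS: {V0: 0.0, tau_r: 0.25, tau_d: 1.0}
  IB_SI: {V0: 0.0, tau_r: 2.5, tau_d: 1.0}
  a_db: {V0: 0.0, tau_r: 0.25, tau_d: 100.0}
  SI_RSout: {V0: 0.0, tau_r: 0.25, tau_d: 1.0}

synapse_conductances:
  RS_FS: 0.5
  RS_SI: 0.4
  FS_RS: 1.0
  FS_SI: 1.0
  FS_FS: 1.0
  SI_SI: 2.0
  SI_SI_solo: 4.0
  input2_SI_solo: 1.5
  SI_IB: 8.0
  IB_FS: 0.5
  IB_SI: 0.3
  a_db: 0.25
  SI_RSout: 0.8
  input1_RS: 0.5

variants:
  # faster dendritic h-current kinetics (used for the multi-branch
  # interburst-map runs)
  fast_h:
    cells.IB_da.tau_scale.m_AR: "*0.75"
    cells.IB_db.tau_scale.m_AR: "*0.75"
  # weaker FS->SI synapse: shorter effective inhibition window c
  weak_fs_si:
    synapse_conductances.FS_SI: "*0.6"
  # doubled input-1 strength: SI can fire on every input-1 cycle (m = 1)
  strong_input1:
    synapse_conductances.RS_SI: "*2.0"
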