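# Default parameter set for the coupled EC/SMC pathway model.
# One entry per line:  symbol  value  unit  description
# Units are uM (micromolar), mV, s throughout; fluxes in uM/s.
# SMC = smooth muscle cell, EC = endothelial cell.

# --- SMC: IP3-induced store release and CICR -------------------------------
F_smc        0.23      uM/s      max IP3R-mediated Ca flux from SR (SMC)
Kr_smc       1.0       uM        half-saturation IP3 concentration for IP3R (SMC)
B_smc        2.025     uM/s      max SERCA uptake rate into SR (SMC)
cb_smc       1.0       uM        half-saturation cytosolic Ca for SERCA (SMC)
C_smc        55.0      uM/s      max CICR flux from SR (SMC)
sc_smc       2.0       uM        half-saturation store Ca for CICR (SMC)
cc_smc       0.9       uM        half-saturation cytosolic Ca for CICR (SMC)
D_smc        0.24      1/s       Ca extrusion (ATPase) rate constant (SMC)
vd_smc       -100.0    mV        extrusion voltage offset (SMC)
Rd_smc       250.0     mV        extrusion voltage slope (SMC)
L_smc        0.025     1/s       SR leak rate constant (SMC)

# --- SMC: membrane fluxes --------------------------------------------------
G_Ca         0.00129   uM/mV/s   whole-cell VOCC conductance (SMC)
v_Ca1        100.0     mV        VOCC reversal potential
v_Ca2        -24.0     mV        VOCC half-activation potential
R_Ca         8.5       mV        VOCC activation slope
G_NaCa       0.00316   uM/mV/s   Na+/Ca2+ exchanger conductance (SMC)
c_NaCa       0.5       uM        NaCa half-saturation cytosolic Ca
v_NaCa       -30.0     mV        NaCa reversal potential
F_NaK        0.0432    uM/s      Na+/K+-ATPase current (constant, SMC)
G_Cl         0.00134   uM/mV/s   Cl- channel conductance (SMC)
v_Cl         -25.0     mV        Cl- reversal potential
G_K          0.00446   uM/mV/s   Ca-activated K channel conductance (SMC)
v_K          -94.0     mV        K+ reversal potential (SMC)
gamma_smc    1970.0    mV/uM     scaling ion flux -> membrane potential rate (SMC)

# --- SMC: K-channel gating and IP3 kinetics --------------------------------
lambda_w     45.0      1/s       K-channel open-fraction relaxation rate (SMC)
c_w          0.0       uM        Ca shift in K-channel activation
beta_w       0.13      uM^2      K-channel activation scale
v_Ca3        -27.0     mV        K-channel half-activation potential
R_K          12.0      mV        K-channel activation slope
k_ip3_smc    0.1       1/s       IP3 degradation rate constant (SMC)

# --- EC: stores, CICR, extrusion -------------------------------------------
F_ec         0.23      uM/s      max IP3R-mediated Ca flux from ER (EC)
Kr_ec        1.0       uM        half-saturation IP3 concentration for IP3R (EC)
B_ec         0.5       uM/s      max SERCA uptake rate into ER (EC)
cb_ec        1.0       uM        half-saturation cytosolic Ca for SERCA (EC)
C_ec         5.0       uM/s      max CICR flux from ER (EC)
sc_ec        2.0       uM        half-saturation store Ca for CICR (EC)
cc_ec        0.9       uM        half-saturation cytosolic Ca for CICR (EC)
D_ec         0.24      1/s       Ca extrusion rate constant (EC)
L_ec         0.025     1/s       ER leak rate constant (EC)
k_ip3_ec     0.1       1/s       IP3 degradation rate constant (EC)
J0_ec        0.029     uM/s      constant background Ca influx (EC)

# --- EC: non-selective cation channel --------------------------------------
G_cat        0.00066   uM/mV/s   Ca-activated non-selective cation conductance (EC)
E_Ca         50.0      mV        cation channel reversal potential
m3_cat       -0.18     log10(uM) cation activation midpoint (log10 cytosolic Ca)
m4_cat       0.37      log10(uM) cation activation slope

# --- EC: membrane potential -------------------------------------------------
C_m_ec       25.8      pF        EC membrane capacitance
G_tot_ec     6927.0    pS        total BKCa conductance (EC)
v_K_ec       -80.0     mV        K+ reversal potential (EC)
a1_bk        53.3      -         BKCa activation constant a1
a2_bk        53.3      -         BKCa activation constant a2
b_bk         -80.8     mV        BKCa activation offset potential
c_bk         -0.4      log10(uM) BKCa Ca midpoint (log10 cytosolic Ca)
m3_bk        0.00132   -         BKCa activation denominator quadratic weight
m4_bk        0.3       -         BKCa activation denominator offset
m3_sk        -0.28     log10(uM) SKCa Ca midpoint (log10 cytosolic Ca)
m4_sk        0.389     log10(uM) SKCa activation slope
G_R_ec       955.0     pS        residual (leak) conductance (EC)
v_rest_ec    -31.1     mV        residual current reversal potential (EC)
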