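"""Independent straight-line oracle transcriptions used by the tests.

These functions re-derive the model quantities directly from the published
constant table and equation forms, written deliberately without reference
to the library code so they can serve as an independent check.
"""

import math

# constant table, transcribed literally
C_E = 1.27e-3
C_N = 8.85
CYT_JMAX = 172.0
E_ATP = 4.0 / 3.0
F_SPECTRAL = 0.15
ALPHA = 0.84
THETA = 0.7
JMAX_CL = 3.0
N_CHL = 0.0158887
PSI = 2.0
PSII = 2.5
PI_CHL = 184.0
PII_CHL = 60.0
L_CHL = 13.0
PI_N = 32.8
PII_N = 83.3
L_N = 26.0
MW_PEPC = 96000.0
MW_PPDK = 95000.0
KCAT_PEPC = 66.0
KCAT_PPDK = 6.02


def nitrogen_chain(n_etot, n_c4, n_jmax, p, n_ps):
    """Straight-line transcription of the capacity equations.

    Returns a dict with E_tot, V_pmax, Chl, the thylakoid composition and
    both Jmax values for a feasible (non-negative LHC) input.
    """
    e_tot = n_etot * n_ps * C_E

    mw_star_ppdk = 0.16 * MW_PPDK / 14.0
    mw_star_pepc = 0.16 * MW_PEPC / 14.0
    v_pmax = n_c4 * n_ps / (mw_star_ppdk / KCAT_PPDK + mw_star_pepc / KCAT_PEPC)

    chl = N_CHL * n_jmax * n_ps

    psi_let = 2.0 * p
    psi_cet = 2.0 * (1.0 - p)
    psii = 2.5
    lhc_let = (1000.0 * p - psii * PII_CHL - psi_let * PI_CHL) / L_CHL
    lhc_cet = (1000.0 * (1.0 - p) - psi_cet * PI_CHL) / L_CHL

    out = {
        "E_tot": e_tot,
        "V_pmax": v_pmax,
        "Chl": chl,
        "PSI_LET": psi_let,
        "PSI_CET": psi_cet,
        "PSII": psii,
        "LHC_LET": lhc_let,
        "LHC_CET": lhc_cet,
    }
    if chl <= 0:
        out.update(
            N_thy_LET=0.0, N_LH_LET=0.0, cyt_LET=0.0, Jmax_LET=0.0,
            N_thy_CET=0.0, N_LH_CET=0.0, cyt_CET=0.0, Jmax_CET=0.0,
        )
        return out

    n_thy_let = n_jmax * n_ps * p / chl
    n_lh_let = (
        psii * PII_N * PII_CHL * 1e-3
        + psi_let * PI_N * PI_CHL * 1e-3
        + lhc_let * L_N * L_CHL * 1e-3
    )
    cyt_let = (n_thy_let - n_lh_let) / C_N
    jmax_let = max(0.0, cyt_let * chl * CYT_JMAX / 1000.0)

    n_thy_cet = n_jmax * n_ps * (1.0 - p) / chl
    n_lh_cet = psi_cet * PI_N * PI_CHL * 1e-3 + lhc_cet * L_N * L_CHL * 1e-3
    cyt_cet = (n_thy_cet - n_lh_cet) / C_N
    jmax_cet = max(0.0, cyt_cet * chl * CYT_JMAX * JMAX_CL / 1000.0)

    out.update(
        N_thy_LET=n_thy_let,
        N_LH_LET=n_lh_let,
        cyt_LET=cyt_let,
        Jmax_LET=jmax_let if p > 0 else 0.0,
        N_thy_CET=n_thy_cet,
        N_LH_CET=n_lh_cet,
        cyt_CET=cyt_cet,
        Jmax_CET=jmax_cet if p < 1 else 0.0,
    )
    return out


def hyperbola(i_abso, jmax, theta=THETA):
    """Quadratic-formula evaluation of the light-response hyperbola."""
    if i_abso == 0 or jmax == 0:
        return 0.0
    s = i_abso + jmax
    return (s - math.sqrt(s * s - 4.0 * theta * i_abso * jmax)) / (2.0 * theta)


def peaked_arrhenius(t_k, k25, e, h, s, r=8.314):
    """Literal transcription of the extended Arrhenius response."""
    value = k25 * math.exp(e * (t_k - 298.15) / (298.15 * r * t_k))
    if not math.isinf(h):
        value *= (1.0 + math.exp((298.15 * s - h) / (298.15 * r))) / (
            1.0 + math.exp((t_k * s - h) / (t_k * r))
        )
    return value


def farquhar_c3_enzyme(vcmax, c_m, o_mbar, k_c, k_o, s_co):
    """Single-compartment enzyme-limited C3 rate.

    ``A = Vcmax * Cm / (Cm + Kc (1 + O/Ko)) * (1 - Gamma*/Cm)`` with the
    compensation point ``Gamma* = 0.5 * O / S_co`` (O converted to ubar).
    """
    gamma = 500.0 * o_mbar / s_co
    return vcmax * c_m / (c_m + k_c * (1.0 + o_mbar / k_o)) * (1.0 - gamma / c_m)


def c3_light_limited(j_let, j_cet, c_m, o_mbar, s_co, fractions,
                     e_atp=E_ATP, h_per_atp=4.0):
    """Energy-budget C3 light-limited rate for an all-mesophyll leaf.

    ``fractions = (f_cb, f_pr)`` of the supply to the mesophyll
    Calvin-Benson and photorespiration pools.  Returns (A_atp, A_nadph).
    """
    gamma = 500.0 * o_mbar / s_co
    phi = 2.0 * gamma / c_m
    atp = j_let / e_atp + j_cet * 2.0 / h_per_atp
    nadph = j_let / 2.0
    f_cb, f_pr = fractions

    vc_atp = f_cb * atp / 3.0
    if phi > 0:
        vc_atp = min(vc_atp, f_pr * atp / (3.5 * phi))
    vc_nadph = f_cb * nadph / 2.0
    if phi > 0:
        vc_nadph = min(vc_nadph, f_pr * nadph / (2.0 * phi))
    return vc_atp * (1.0 - 0.5 * phi), vc_nadph * (1.0 - 0.5 * phi)
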