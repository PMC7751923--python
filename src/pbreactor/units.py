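"""Unit conversion constants between bench units and canonical SI.

Internal convention: geometry and transport in SI (m, s, kg); concentrations
in mM, which is numerically identical to mol/m3, so no conversion factor is
needed between the two. I/O layers accept the bench units used at the rig
(mL/min, cm, mm, mg, mM, min) and convert at the boundary.
"""

ML_MIN_TO_M3_S = 1e-6 / 60.0
CM_TO_M = 1e-2
MM_TO_M = 1e-3
ML_TO_M3 = 1e-6
MG_TO_KG = 1e-6
MIN_TO_S = 60.0


def ml_min_to_m3_s(q_ml_min: float) -> float:
    return q_ml_min * ML_MIN_TO_M3_S


def m3_s_to_ml_min(q_m3_s: float) -> float:
    return q_m3_s / ML_MIN_TO_M3_S
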