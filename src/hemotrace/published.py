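"""Published STEMI/PPCI cohort summary used to parameterize and cross-check.

These are the printed group summaries of a 605-patient cohort (554 one-year
survivors, 51 deaths) treated with primary PCI. They serve two purposes:

- the synthetic cohort generator targets these prevalences and effect sizes;
- the effect-size machinery in :mod:`hemotrace.stats` is validated by
  recomputing φ from the printed 2×2 counts.

Counts are (present & survived, present & died); the complement rows follow
from the group totals. The printed weight/height rows carry transposed labels
(171.65 "kg" with 85.64 "cm"); they are stored here under the physically
plausible assignment: height 171.65 ± 10.76 cm, weight 85.64 ± 20.13 kg.
"""

from __future__ import annotations

from .stats import ContingencyTable2x2

N_TOTAL = 605
N_DIED = 51
N_SURVIVED = 554

#: printed 1-year mortality prevalence, percent
MORTALITY_PERCENT = 8.43


def mortality_table() -> dict[str, int]:
    return {"n_total": N_TOTAL, "n_died": N_DIED, "n_survived": N_SURVIVED}


def _table(present_survived: int, present_died: int) -> ContingencyTable2x2:
    return ContingencyTable2x2(
        a=present_survived,
        b=present_died,
        c=N_SURVIVED - present_survived,
        d=N_DIED - present_died,
    )


#: binary risk factors: printed (present & survived, present & died) counts
BINARY_FACTORS: dict[str, ContingencyTable2x2] = {
    "male": _table(405, 27),
    "hypertension": _table(314, 35),
    "diabetes": _table(139, 17),
    "dyslipidemia": _table(230, 16),
    "stroke_tia": _table(21, 7),
    "pvd": _table(15, 4),
    "renal_dysfunction": _table(24, 14),
    "dialysis": _table(1, 4),
    "ihd_history": _table(108, 8),
    "pci_cabg": _table(85, 5),
}

#: printed effect sizes (|φ|) for the binary rows
PRINTED_PHI: dict[str, float] = {
    "male": 0.13,
    "hypertension": 0.07,
    "diabetes": 0.05,
    "dyslipidemia": 0.06,
    "stroke_tia": 0.13,
    "pvd": 0.08,
    "renal_dysfunction": 0.26,
    "dialysis": 0.24,
    "ihd_history": 0.03,
    "pci_cabg": 0.04,
}

#: continuous covariates: (mean, sd) overall / survivors / deaths, printed d
CONTINUOUS: dict[str, dict] = {
    "age": {
        "total": (64.19, 13.18),
        "survived": (63.56, 12.10),
        "died": (70.96, 13.38),
        "printed_d": 0.57,
    },
    "height_cm": {
        "total": (171.65, 10.76),
        "survived": (171.93, 10.68),
        "died": (168.73, 11.27),
        "printed_d": 0.30,
    },
    "weight_kg": {
        "total": (85.64, 20.13),
        "survived": (86.24, 19.99),
        "died": (79.15, 20.69),
        "printed_d": 0.35,
    },
    "esp_s_per_min": {
        "total": (19.11, 3.29),
        "survived": (19.19, 3.23),
        "died": (18.31, 3.82),
        "printed_d": 0.27,
    },
    "est_s_per_beat": {
        "total": (0.24, 0.04),
        "survived": (0.24, 0.04),
        "died": (0.22, 0.05),
        "printed_d": 0.46,
    },
}

#: exposure prevalence (fraction of the cohort with the factor present)
def exposure_rate(factor: str) -> float:
    t = BINARY_FACTORS[factor]
    return (t.a + t.b) / t.n
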