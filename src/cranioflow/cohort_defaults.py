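"""Normative group-level flow parameters for synthetic cohorts.

Published normative values for healthy young (HYV, n=16, ~31 y) and
healthy elderly (HEV, n=19, ~73 y) adults measured with cine PC-MRI:
composite mean flows (ml/min), blood and CSF stroke volumes (ml per
cardiac cycle), pooled-tree pulsatility indices, and heart rate (bpm).
Each entry is (mean, SD); the cohort generator draws per-subject values
from these normals.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

__all__ = ["NORMATIVE_GROUPS", "GROUP_SIZES"]

GROUP_SIZES = {"HYV": 16, "HEV": 19}

NORMATIVE_GROUPS: Dict[str, Mapping[str, Tuple[float, float]]] = {
    "HYV": {
        "extra_acbf": (716.0, 129.0),
        "intra_acbf": (670.0, 158.0),
        "extra_vcbf": (449.0, 173.0),
        "intra_vcbf": (478.0, 94.0),
        "extra_blood_sv": (0.91, 0.39),
        "intra_blood_sv": (0.76, 0.30),
        "spinal_csf_sv": (0.34, 0.21),
        "aqueductal_csf_sv": (0.04, 0.02),
        "extra_arterial_pi": (0.85, 0.17),
        "intra_arterial_pi": (0.77, 0.22),
        "extra_venous_pi": (0.47, 0.25),
        "intra_venous_pi": (0.25, 0.16),
        "heart_rate": (69.0, 14.0),
    },
    "HEV": {
        "extra_acbf": (588.0, 119.0),
        "intra_acbf": (593.0, 107.0),
        "extra_vcbf": (533.0, 161.0),
        "intra_vcbf": (379.0, 88.0),
        "extra_blood_sv": (0.98, 0.32),
        "intra_blood_sv": (1.08, 0.21),
        "spinal_csf_sv": (0.51, 0.20),
        "aqueductal_csf_sv": (0.05, 0.03),
        "extra_arterial_pi": (1.31, 0.32),
        "intra_arterial_pi": (1.16, 0.17),
        "extra_venous_pi": (0.86, 0.40),
        "intra_venous_pi": (0.52, 0.16),
        "heart_rate": (70.0, 11.0),
    },
}
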