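"""Reference metric values reported for the transcribed designs.

These are the published third-order aberration and MTF readings that
accompany the packaged prescriptions (produced by the original CODE V-based
workflow).  They are inputs for improvement-rate comparisons, not outputs of
this package: this tracer does not reproduce CODE V's proprietary
aberration normalisation, so numerical equality with these values is never
asserted — only the arithmetic identities and orderings built on them.

Keys: design stage -> pupil diameter (mm) -> metric.
"""

from __future__ import annotations

#: SA / TCO / RMS readings per design stage and analysis pupil.
THIRD_ORDER: dict[str, dict[int, dict[str, float]]] = {
    "initial": {
        5: {"SA": -0.016148, "TCO": -0.033068, "RMS": 0.005315},
        6: {"SA": -0.027904, "TCO": -0.047618, "RMS": 0.01264},
    },
    "myopic": {
        5: {"SA": -0.073302, "TCO": -0.052464, "RMS": 0.537989},
        6: {"SA": -0.126666, "TCO": -0.075548, "RMS": 0.698584},
    },
    "codev": {
        5: {"SA": 0.01, "TCO": -0.0162, "RMS": 0.032718},
        6: {"SA": 0.01, "TCO": -0.01781, "RMS": 0.038357},
    },
    "ga": {
        5: {"SA": 0.032994, "TCO": -0.011763, "RMS": 0.020633},
        6: {"SA": 0.014618, "TCO": -0.010201, "RMS": 0.031816},
    },
}

#: Geometric-MTF readings at 10/20/30 lp/mm per design stage and pupil.
MTF: dict[str, dict[int, dict[float, float]]] = {
    "myopic": {
        5: {10.0: 0.003, 20.0: 0.001, 30.0: 0.0},
        6: {10.0: 0.005, 20.0: 0.0, 30.0: 0.007},
    },
    "codev": {
        5: {10.0: 0.768, 20.0: 0.356, 30.0: 0.145},
        6: {10.0: 0.695, 20.0: 0.253, 30.0: 0.115},
    },
    "ga": {
        5: {10.0: 0.901, 20.0: 0.657, 30.0: 0.389},
        6: {10.0: 0.783, 20.0: 0.391, 30.0: 0.177},
    },
}
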