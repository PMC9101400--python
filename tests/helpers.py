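"""Shared experiment protocols for the recovery tests."""

import numpy as np
from scipy.signal import savgol_filter

from pollenraman import PreprocessConfig, builtin_templates
from pollenraman.preprocess import _rubberband_row


def no_qc_config() -> PreprocessConfig:
    """Full preprocessing chain with the quality filter disabled.

    Used by the clustering/unmixing recovery experiments so substrate
    pixels stay in and all five regions and templates are identifiable.
    """
    return PreprocessConfig(stages=("interpolate", "rubberband", "despike",
                                    "normalize", "smooth"))


def corrected_templates(comps, axis) -> np.ndarray:
    """Pure templates passed through the chain's per-spectrum corrections.

    Rubberband removes the Lorentzian-tail pedestal of any spectrum, so the
    endmembers recoverable from corrected data are the corrected templates,
    not the raw ones.
    """
    S = comps.matrix(axis)
    x = axis.values
    out = []
    for row in S:
        c = row - _rubberband_row(x, row)
        c = savgol_filter(c, 9, 2, mode="interp")
        c = np.clip(c, 0.0, None)
        c = c / np.trapezoid(c, x)
        out.append(c)
    return np.stack(out)
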