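import numpy as np


def chord_residual(curve):
    """Max perpendicular distance of (E, Gamma) samples from their chord."""
    pts = curve.samples[["E", "Gamma"]].to_numpy()
    d = pts[-1] - pts[0]
    norm = np.linalg.norm(d)
    if norm == 0:
        return 0.0
    d = d / norm
    rel = pts - pts[0]
    return float(np.max(np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])))
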