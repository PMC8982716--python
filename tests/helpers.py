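import numpy as np

from cgmdrnn.simulate import SubjectSeries


def make_series(glucose, valid=None):
    """Bare-bones SubjectSeries around a glucose array (no events)."""
    g = np.asarray(glucose, dtype=float)
    return SubjectSeries(
        subject_id="t",
        start_time=np.datetime64("2024-01-01T00:00"),
        glucose=g,
        bolus=np.zeros_like(g),
        meal=np.zeros_like(g),
        valid_mask=np.ones(len(g), bool) if valid is None else np.asarray(valid, bool),
    )
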