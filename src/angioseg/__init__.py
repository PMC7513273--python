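"""Spatio-temporal coronary vessel segmentation for X-ray angiographic video.

The package trains a 3D-2D convolutional network: a temporal-fusion 3D input
layer collapses a window of 2N+1 consecutive frames into 2D feature maps,
which a CE-Net-style encoder/decoder turns into a vessel mask for the central
frame.  A built-in simulator generates synthetic angiographic sequences with
ground truth so every stage is testable without clinical data.
"""

__version__ = "0.1.0"

__all__ = ["VesselSegmenter", "VesselTreeSpec", "SyntheticSequence",
           "render_sequence", "__version__"]

_LAZY = {
    "VesselSegmenter": "angioseg.estimator",
    "VesselTreeSpec": "angioseg.simulate",
    "SyntheticSequence": "angioseg.simulate",
    "render_sequence": "angioseg.simulate",
}


def __getattr__(name):
    if name in _LAZY:
        import importlib

        return getattr(importlib.import_module(_LAZY[name]), name)
    raise AttributeError(f"module 'angioseg' has no attribute {name!r}")
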