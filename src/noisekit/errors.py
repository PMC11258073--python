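"""Typed errors raised by the pipeline.

Each failure mode a caller may want to catch and record (rather than crash on)
gets its own class; `run_study` converts them into failed study records.
"""


class NoisekitError(Exception):
    """Base class for all package errors."""


class GeometryError(NoisekitError):
    """Phantom geometry does not fit inside the requested volume shape."""


class SpacingError(NoisekitError):
    """Missing, non-positive or inconsistent voxel-spacing metadata."""


class DicomSeriesError(NoisekitError):
    """A DICOM series is inconsistent (mixed shapes, spacings or orientations)."""


class ContactNotFound(NoisekitError):
    """No aorta voxel is in-plane adjacent to the LM segmentation.

    Mirrors the single real-world failure mode where the left main ostium
    cannot be located (e.g. anomalous LM origin) and no measurement is made.
    """


class ZoneEmpty(NoisekitError):
    """Every candidate slice of the measurement zone shrank to the empty set."""


class TrainingDiverged(NoisekitError):
    """Training loss became non-finite."""
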