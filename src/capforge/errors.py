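"""Exception hierarchy for the scaffold design pipeline."""


class CapforgeError(Exception):
    """Base class for all package errors."""


class PathParseError(CapforgeError):
    """A centerline CSV row could not be parsed; carries the 1-based line."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class InvalidPathError(CapforgeError):
    """Centerline path violates its invariants (too few points, duplicates...)."""


class SpecError(CapforgeError):
    """A design spec (capillary, support, chip) violates its invariants."""


class DegenerateGridError(CapforgeError):
    """Pore pitch too large for both the path length and the circumference."""


class PoreMergeError(CapforgeError):
    """A pore opening would vanish or merge with its neighbour."""


class MeshError(CapforgeError):
    """Mesh-level failure (non-manifold input, impossible decimation...)."""


class ImagingError(CapforgeError):
    """QC image analysis failure (shape mismatch, constant image...)."""


class ConfigError(CapforgeError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))
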