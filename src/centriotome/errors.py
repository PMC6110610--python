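"""Exception types shared across the pipeline stages."""


class CentriotomeError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(CentriotomeError, ValueError):
    """A model/lattice/decoration specification violates its invariants."""


class ConfigError(CentriotomeError, ValueError):
    """A run configuration is malformed or references unknown presets."""


class RodDeficitError(CentriotomeError):
    """Automatic rod tracing found fewer than the expected nine rods."""

    def __init__(self, found: int, expected: int = 9):
        self.found = found
        self.expected = expected
        super().__init__(f"traced {found} rods, expected {expected}")


class OrientationDegenerateError(CentriotomeError):
    """Rod tangent parallel to the radial direction: frame undefined."""


class OutOfBoundsError(CentriotomeError, ValueError):
    """Requested sub-volume center lies outside the tomogram."""


class EmptyOverlapError(CentriotomeError):
    """Constrained correlation has no sampled Fourier region in common."""


class EmptySetError(CentriotomeError, ValueError):
    """An averaging/classification operation received zero particles."""


class AmbiguousPeriodError(CentriotomeError):
    """Decoration periodicity detection could not separate the candidates."""


class FitDegenerateError(CentriotomeError):
    """Ellipse/axis fit is under-determined (collinear or too few points)."""
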