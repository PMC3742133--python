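"""Exception hierarchy shared across the pipeline.

``FormatError`` and ``ConfigError`` map to exit code 2 in the CLI; everything
else is an ordinary failure (exit code 1).
"""


class PPMScreenError(Exception):
    """Base class for all ppmscreen errors."""


class FormatError(PPMScreenError, ValueError):
    """An input file or argument violates the expected format."""


class BoundaryError(PPMScreenError, ValueError):
    """A promoter window overhangs its contig; never silently truncated."""


class ContigNotFoundError(PPMScreenError, KeyError):
    """A transcript references a contig absent from the genome."""


class PlacementError(PPMScreenError, RuntimeError):
    """Motif planting could not find a clean placement within the retry budget."""


class ConfigError(PPMScreenError, ValueError):
    """A generator or pipeline configuration is internally inconsistent."""


class InfeasibleError(PPMScreenError, ValueError):
    """The requested motif arrangement cannot fit in the window."""


class StatError(PPMScreenError, ValueError):
    """A statistical routine was called on a degenerate table."""
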