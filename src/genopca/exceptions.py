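"""Exception hierarchy.

All package errors derive from :class:`GenopcaError` so callers can catch one
type; the CLI maps subclasses onto exit codes (usage=2, data format=3,
numerical failure=4).
"""


class GenopcaError(Exception):
    """Base class for all genopca errors."""


class ParameterError(GenopcaError, ValueError):
    """Invalid user-supplied parameter (bad k/l, thresholds out of range...)."""


class FormatError(GenopcaError, ValueError):
    """Malformed input file (bad PLINK magic, truncated .bed, ragged .bim)."""


class DimensionError(GenopcaError, ValueError):
    """Operand shapes incompatible with the planned operation."""


class AlphabetError(GenopcaError, ValueError):
    """Matrix entry outside the {0, 1, 2} genotype alphabet."""


class RankError(GenopcaError, ValueError):
    """A matrix that must be full rank is (numerically) singular."""


class DegenerateSnpError(GenopcaError, ValueError):
    """A SNP with zero variance reached a step that requires variation."""


class EmptyPanelError(GenopcaError, ValueError):
    """QC filtering removed every SNP."""


class AlignmentError(GenopcaError, ValueError):
    """Sample sets/orders of two inputs do not match."""


class DegenerateScanError(GenopcaError, ValueError):
    """Selection scan encountered a zero-variance projection column."""
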