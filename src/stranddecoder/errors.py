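"""Exception hierarchy for the decoder toolkit.

Every stage raises a subclass of :class:`StrandDecoderError` so that pipeline
callers can attach stage provenance without string-matching messages.
"""


class StrandDecoderError(Exception):
    """Base class for all package errors."""


class DefinitionError(StrandDecoderError):
    """Unknown star allele, locus, or panel member."""


class UnsupportedPanelError(StrandDecoderError):
    """Panel violates a structural assumption (e.g. non-biallelic locus)."""


class ConsistencyError(StrandDecoderError):
    """Identical genetic codes labelled with different phenotype classes."""


class ParseError(StrandDecoderError):
    """Malformed input file."""


class DimensionError(StrandDecoderError):
    """Mismatched panels or vector lengths."""


class InfeasibilityError(StrandDecoderError):
    """No coefficient array satisfies the class-interval constraints.

    ``conflict`` optionally carries a minimal conflicting genotype pair.
    """

    def __init__(self, message, conflict=None):
        super().__init__(message)
        self.conflict = conflict


class CompileError(StrandDecoderError):
    """Invalid compiler input (empty weights, bad base unit, namespaces)."""


class UnsupportedEncodingError(CompileError):
    """Encoding cannot represent the requested weights (e.g. negative lnOR
    in the literal ternary dosage encoding)."""


class WiringError(StrandDecoderError):
    """Input species or gate reference not present in the circuit."""


class IntegrationError(StrandDecoderError):
    """ODE solver failed to converge."""


class CalibrationError(StrandDecoderError):
    """Missing fluorophore in a calibration curve."""


class ConfigError(StrandDecoderError):
    """Invalid configuration value."""


class InputError(StrandDecoderError):
    """Invalid runtime input (missing channel, degenerate value...)."""


class GenerationError(StrandDecoderError):
    """Sequence generator exhausted its attempt budget."""


class CohortSizeError(StrandDecoderError):
    """Cohort too small for the requested stratification."""
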