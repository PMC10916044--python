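"""Exception hierarchy for epickit."""


class EpickitError(Exception):
    """Base class for all epickit errors."""


class ManifestFormatError(EpickitError):
    """A manifest file violates the expected Illumina/SeSAMe layout."""


class IlmnIDParseError(EpickitError):
    """An IlmnID suffix is present but malformed."""


class UndesignableError(EpickitError):
    """A probe cannot be (re)designed from its Forward_Sequence context."""


class AlignmentInputError(EpickitError):
    """Bad input to the probe aligner or PSL reader."""


class DegenerateFitError(EpickitError):
    """A row-linear fit is degenerate (zero consensus variance, too few samples)."""
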