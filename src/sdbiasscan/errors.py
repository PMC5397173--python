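"""Named exception types for input validation and analysis preconditions."""


class SdbiasscanError(Exception):
    """Base class for all package errors."""


class InputError(SdbiasscanError):
    """Malformed or inconsistent user input (files, coordinates, alphabets)."""


class UnknownContigError(InputError):
    """Annotation references a contig absent from the genome."""


class CoordinateError(InputError):
    """CDS coordinates are malformed (non-numeric, start > end, out of range)."""


class EmptyTailError(InputError):
    """The 16S rRNA 3' tail sequence is empty or too short."""


class AlphabetError(InputError):
    """Sequence contains characters outside the expected alphabet."""


class DegenerateInputError(SdbiasscanError):
    """An analysis precondition is unmet (empty gene set, zero variance, ...)."""


class EngineUnavailableError(SdbiasscanError):
    """A requested external computation engine could not be loaded."""
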