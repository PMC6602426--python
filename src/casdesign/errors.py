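"""Exception hierarchy shared by all casdesign modules."""


class CasDesignError(Exception):
    """Base class for all errors raised by casdesign."""


class FastaFormatError(CasDesignError):
    """Malformed FASTA input (duplicate headers, empty file, ...)."""


class AlphabetError(CasDesignError):
    """Sequence contains a character outside the nucleotide alphabet."""


class AnnotationError(CasDesignError):
    """Inconsistent gene annotation (orphan Parent references, ...)."""


class CoordinateError(CasDesignError):
    """A coordinate or interval falls outside its sequence."""


class ContractError(CasDesignError):
    """A function was called in violation of its documented contract."""


class StaleIndexError(CasDesignError):
    """An on-disk k-mer index does not match the sequences it is used with."""


class ControlExhaustionError(CasDesignError):
    """Could not generate the requested number of control guides."""


class CapacityError(CasDesignError):
    """A synthetic fixture request does not fit in the requested genome."""
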