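"""Exception hierarchy shared across the package."""


class MatlociError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MatlociError):
    """Malformed input file (FASTA, Newick, TSV manifest, GFF3)."""


class ValidationError(MatlociError):
    """Inputs violate a documented invariant or precondition."""
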