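"""Exception hierarchy shared by all tyrscan modules."""


class TyrscanError(Exception):
    """Base class for all package errors."""


class FormatError(TyrscanError):
    """Malformed input file (unequal FASTA lengths, bad table layout...)."""


class AnnotationError(TyrscanError):
    """Region annotation inconsistent with the alignment (overlaps, bad frame)."""


class PhasingError(TyrscanError):
    """Unphased genotype where phased haplotypes are required."""


class MapError(TyrscanError):
    """Genetic-map problem that cannot be resolved by flat extrapolation."""


class SampleSizeError(TyrscanError):
    """Too few chromosomes for the requested statistic."""


class JCDomainError(TyrscanError):
    """Raw distance outside the Jukes-Cantor correction domain (p >= 3/4)."""


class FrameError(TyrscanError):
    """Coding sequence violates the reading frame (internal stop, length % 3)."""


class ConfigError(TyrscanError):
    """Invalid run or model configuration."""
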