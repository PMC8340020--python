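"""Exception hierarchy.

Every error the library raises derives from :class:`Cdr3VecError` so callers
can catch the whole family; fine-grained subclasses exist where the caller is
expected to branch (e.g. out-of-vocabulary vs. corrupt model).
"""


class Cdr3VecError(Exception):
    """Base class for all cdr3vec errors."""


class FormatError(Cdr3VecError):
    """Input file does not conform to the named standard (e.g. missing column)."""


class FrameError(Cdr3VecError):
    """Nucleotide junction length is not divisible by 3."""


class AlphabetError(Cdr3VecError):
    """Sequence contains characters outside the expected alphabet."""


class TooShortError(Cdr3VecError):
    """Sequence too short for the requested operation (trimming, embedding)."""


class VCallParseError(Cdr3VecError):
    """v_call/j_call string does not match the locus+family grammar."""


class TrainingError(Cdr3VecError):
    """Embedding training cannot proceed (empty corpus, empty vocabulary)."""


class OOVError(Cdr3VecError, KeyError):
    """An n-gram is absent from the trained vocabulary."""


class NotEmbeddableError(OOVError):
    """A whole sequence cannot be embedded because some token is OOV."""


class CorruptModelError(Cdr3VecError):
    """Persisted model file is internally inconsistent."""


class ZeroVarianceError(Cdr3VecError):
    """Attribute values are constant; the statistic is undefined."""


class NoNeighborsError(Cdr3VecError):
    """Spatial weight matrix is identically zero (S0 = 0)."""


class UndefinedVarianceError(Cdr3VecError):
    """Pooled variance undefined (all clusters are singletons)."""


class ConfigError(Cdr3VecError):
    """Invalid or infeasible configuration."""


class StratificationError(Cdr3VecError):
    """A class is missing from a stratified split."""
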