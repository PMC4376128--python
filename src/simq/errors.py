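"""Exception hierarchy for the simq pipeline."""


class SimQError(Exception):
    """Base class for all simq errors."""


class EmptyQuestionError(SimQError):
    """Raised when a question is empty or whitespace/punctuation only."""


class LexiconError(SimQError):
    """Raised for unreadable or empty concept lexicons."""


class ParseFixtureError(SimQError):
    """Raised when a dependency fixture is missing or inconsistent with the tokens."""


class FeatureInputError(SimQError):
    """Raised when a feature kind is requested without its required inputs."""


class KindMismatchError(SimQError):
    """Raised when feature sets of different kinds are compared or indexed together."""


class EvaluationError(SimQError):
    """Raised for malformed gold standards or evaluation inputs."""
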