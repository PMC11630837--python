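"""Exception hierarchy shared by all modules."""


class RepoRankError(Exception):
    """Base class for package errors."""


class InputError(RepoRankError, ValueError):
    """Malformed or inconsistent input data (files, tables, graphs)."""


class ParameterError(RepoRankError, ValueError):
    """Out-of-range or inconsistent run parameters."""


class RunError(RepoRankError, RuntimeError):
    """Failure during an iterative computation (e.g. divergent training)."""


class LogicError(RepoRankError, RuntimeError):
    """Internal contract violation that callers should never trigger."""
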