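"""Exception hierarchy shared across the workbench."""


class QsarError(Exception):
    """Base class for all qsarwb errors."""


class ConfigError(QsarError, ValueError):
    """Invalid configuration value (unknown option, out-of-range parameter)."""


class DomainError(QsarError, ValueError):
    """Input outside the mathematical domain of an operation."""


class SchemaError(QsarError, ValueError):
    """Malformed table or file: missing/duplicated columns, bad shapes."""


class SingularityError(QsarError, ValueError):
    """Rank-deficient design matrix; carries the offending column names."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class EmptyMatrixError(QsarError, ValueError):
    """Pretreatment or filtering removed every column."""


class DisconnectedGraphError(QsarError, ValueError):
    """Topological distances undefined across fragments; carries fragments."""

    def __init__(self, message: str, fragments=None):
        super().__init__(message)
        self.fragments = fragments or []
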