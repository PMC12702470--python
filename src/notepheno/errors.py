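"""Exception and warning types shared across the pipeline."""


class NotephenoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NotephenoError):
    """A configuration value (column map, fraction, path) is invalid."""


class CorpusIntegrityError(NotephenoError):
    """The note corpus violates an integrity constraint (e.g. duplicate note id)."""


class SpecificationError(NotephenoError):
    """A search-pattern specification is empty or normalizes to nothing."""


class FormatError(NotephenoError):
    """A persisted artifact (library, intermediate database) is malformed."""


class UndefinedMetricError(NotephenoError):
    """An accuracy metric has a zero denominator and is undefined."""


class KeyMismatchError(NotephenoError):
    """Two patient-keyed flag maps do not cover the same key set."""

    def __init__(self, only_left: set, only_right: set):
        self.only_left = frozenset(only_left)
        self.only_right = frozenset(only_right)
        super().__init__(
            f"patient key sets differ: {sorted(only_left)!r} only in first, "
            f"{sorted(only_right)!r} only in second"
        )


class StalenessWarning(UserWarning):
    """An intermediate database was built from a different corpus content."""
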