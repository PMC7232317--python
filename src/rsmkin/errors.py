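"""Exception hierarchy shared across the package."""


class RsmkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RsmkinError, ValueError):
    """An argument is non-finite, out of range, or structurally malformed."""


class UnsupportedDesignError(RsmkinError, ValueError):
    """The requested experimental design cannot be constructed."""


class SingularDesignError(RsmkinError, ValueError):
    """The model matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "model matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class UndefinedStatisticError(RsmkinError, ValueError):
    """A requested statistic has no defined value (e.g. zero residual df)."""


class NoFitError(RsmkinError, ValueError):
    """The data admit no model fit (e.g. all concentrations zero)."""


class CorruptedInstallError(RsmkinError, RuntimeError):
    """A bundled data file fails its integrity checksum."""
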