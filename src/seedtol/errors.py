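"""Exception hierarchy shared across the package."""


class SeedtolError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SeedtolError, ValueError):
    """Input violates a documented precondition."""


class SchemaError(SeedtolError, ValueError):
    """A table is missing columns or contains unparseable rows."""


class MissingLevelError(SeedtolError, ValueError):
    """A population × experiment is missing one or more treatment levels."""

    def __init__(self, missing):
        self.missing = list(missing)
        detail = "; ".join(
            f"population={p!r} experiment={e!r} level={l}" for p, e, l in self.missing
        )
        super().__init__(f"missing treatment levels: {detail}")


class JoinError(SeedtolError, ValueError):
    """Population identifiers do not match between two tables."""

    def __init__(self, unmatched, message="unmatched population ids"):
        self.unmatched = sorted(unmatched)
        super().__init__(f"{message}: {self.unmatched}")


class CollinearityError(SeedtolError, ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns, message="rank-deficient design"):
        self.columns = list(columns)
        super().__init__(f"{message}; dependent columns: {self.columns}")
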