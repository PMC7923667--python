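"""Exception types shared across the package.

The distinction between a *validation* failure (bad value supplied by the
caller), a *missing reference* (a commodity lookup that has no entry in a
factor table -- never silently treated as zero), and an *empty group* (a
food group left with no usable commodities after exclusions) matters for
pipeline error reporting, so each gets its own type.
"""


class ValidationError(ValueError):
    """An input value violates a documented precondition or schema."""


class MissingReferenceError(LookupError):
    """A commodity has no entry in a required reference table.

    The message always names the commodity and the table/step involved, so
    audit logs can point users at the exact data-file row to add.
    """

    def __init__(self, commodity: str, table: str):
        self.commodity = commodity
        self.table = table
        super().__init__(f"no entry for commodity {commodity!r} in {table}")


class EmptyGroupError(ValueError):
    """A food group ends up with no commodities carrying positive mass."""
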