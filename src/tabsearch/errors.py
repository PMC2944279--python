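"""Exception hierarchy for tabsearch."""


class TabsearchError(Exception):
    """Base class for all tabsearch errors."""


class ValidationError(TabsearchError, ValueError):
    """An in-memory object violates one of its invariants."""


class InvalidAngleError(ValidationError):
    """Angle passed to the encoder is not a finite number."""


class ParseError(TabsearchError, ValueError):
    """A text input (database file, DSSP file, label file) is malformed.

    Carries the 1-based line number where parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InputError(TabsearchError, ValueError):
    """An input file is unreadable or contains no usable records."""


class EmptyStructureError(TabsearchError):
    """No secondary structure elements survive assignment/filtering.

    Mirrors the convention of omitting structures for which the secondary
    structure assignment finds no SSEs; callers building a database catch
    this and skip the entry.
    """


class DegenerateAxisError(ValidationError):
    """Axis fitting failed because all points coincide."""
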