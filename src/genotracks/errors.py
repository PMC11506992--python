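"""Exception hierarchy.

Schema errors collect every problem found in a table so a user can fix a
CSV in one round trip; the CLI maps each class to a distinct exit code.
"""

from __future__ import annotations


class GenotracksError(Exception):
    """Base class for all package errors."""


class SchemaError(GenotracksError):
    """An input table violates the column contract for its kind.

    ``problems`` holds every violation found in the table, not just the
    first one.
    """

    def __init__(self, kind: str, problems: list[str]):
        self.kind = kind
        self.problems = list(problems)
        msg = f"invalid {kind} table: " + "; ".join(self.problems)
        super().__init__(msg)


class ConfigError(GenotracksError):
    """A configuration value (aesthetics tag, simulation region, ...) is invalid."""


class NothingToPlotError(GenotracksError):
    """No feature survived filtering; there is nothing to draw."""
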