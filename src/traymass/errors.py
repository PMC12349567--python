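"""Exception hierarchy for the tray-mass pipeline."""


class TrayMassError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TrayMassError, ValueError):
    """A physical or configuration specification violates its invariants."""


class CalibrationError(TrayMassError, ValueError):
    """A calibration is degenerate or unidentifiable from the given data."""


class LedgerError(TrayMassError, ValueError):
    """The plant ledger is inconsistent (e.g. removals exceed the count)."""


class SeriesFormatError(TrayMassError, ValueError):
    """A time-series file or container violates the grid/format contract."""
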