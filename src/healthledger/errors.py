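"""Exception hierarchy for the ledger."""


class HealthLedgerError(Exception):
    """Base class for all ledger errors."""


class EnrollmentError(HealthLedgerError):
    """A certificate authority refused an enrollment."""


class PeerUnavailableError(HealthLedgerError):
    """The targeted peer is down; retry against another peer."""


class OrderingError(HealthLedgerError):
    """The ordering service rejected a transaction or block request."""


class CommitError(HealthLedgerError):
    """A block could not be committed (bad linkage, bad authority)."""


class EndorsementError(HealthLedgerError):
    """The endorsement step failed (denial or invalid peer response)."""


class ConfigError(HealthLedgerError):
    """Invalid network or batching configuration."""
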