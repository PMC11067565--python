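"""Exception types shared across the toolkit."""


class AdwhError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(AdwhError):
    """An input table does not have the required shape (missing columns,
    duplicate user ids, ...)."""


class ConfigError(AdwhError):
    """A metric definition, generalization rule or cohort spec is invalid."""


class RefusalError(AdwhError):
    """A safety gate refused to proceed.

    Raised when a direct identifier has no suppress rule, or when an export
    is attempted against a decision that did not allow it.  Refusals are
    deliberate: the caller must change the configuration, never catch and
    continue.
    """
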