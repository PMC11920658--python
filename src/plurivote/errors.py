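"""Exception hierarchy shared across the package."""


class PlurivoteError(Exception):
    """Base class for all package-specific errors."""


class UnparseableLabel(PlurivoteError):
    """A raw token could not be normalized to one of the five sentiment labels."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"not a sentiment label: {raw!r}")


class SchemaError(PlurivoteError):
    """An input table is missing required columns."""


class IntegrityError(PlurivoteError):
    """Messages and response pools disagree (missing pool, wrong length, duplicate id)."""


class MixedMError(PlurivoteError):
    """Per-message accuracies with differing m were aggregated together."""


class ZeroReferenceError(PlurivoteError):
    """Ratio to a reference whose mean accuracy is zero."""


class MissingDecisionError(PlurivoteError):
    """A message lacks a machine decision when building a confusion table."""


class EmptyCategoryError(PlurivoteError):
    """Flow analysis requested for a category with no messages."""


class MissingTextError(PlurivoteError):
    """Prompt construction requires message text, which is absent."""


class RejectedMessage(PlurivoteError):
    """A message was abandoned after repeated unparseable backend responses."""

    def __init__(self, message_id: str, failures: int):
        self.message_id = message_id
        self.failures = failures
        super().__init__(
            f"message {message_id!r} rejected after {failures} unparseable responses"
        )


class BackendError(PlurivoteError):
    """A backend call failed; wraps the original error with the message id."""

    def __init__(self, message_id: str, cause: Exception):
        self.message_id = message_id
        self.cause = cause
        super().__init__(f"backend failure for message {message_id!r}: {cause}")
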