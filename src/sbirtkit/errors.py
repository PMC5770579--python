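"""Exception hierarchy shared across the toolkit."""


class SbirtError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(SbirtError):
    """A configuration document is missing or malformed."""


class InconsistentInterviewError(SbirtError):
    """Recorded responses violate the skip logic or code sets."""


class IncompleteBranchError(SbirtError):
    """A substance branch was scored before all required items were answered."""


class UnknownResponseCodeError(SbirtError):
    """A response code is outside the item's declared code set."""


class StagingError(SbirtError):
    """Staging answers are internally inconsistent (e.g. change date in the future)."""


class GoalNotInMenuError(SbirtError):
    """The chosen goal is not on the stage-matched menu offered."""


class LibrarySchemaError(SbirtError):
    """A content-library document failed validation."""

    def __init__(self, message: str, template_id: str | None = None):
        self.template_id = template_id
        if template_id is not None:
            message = f"template {template_id!r}: {message}"
        super().__init__(message)


class EmptyTextError(SbirtError):
    """Readability was requested for empty text."""


class ScheduleError(SbirtError):
    """A message schedule could not be built as requested."""


class MissingTemplateError(ScheduleError):
    """No library template matches a required schedule slot."""


class AppointmentError(ScheduleError):
    """An appointment cannot be honored (outside horizon or no lead time)."""


class SessionNotFoundError(SbirtError):
    """No stored session matches the lookup key."""


class AmbiguousMatchError(SbirtError):
    """More than one stored session matches the lookup key."""


class OverrideError(SbirtError):
    """A provider override is invalid for the session it targets."""


class UnachievableTargetError(SbirtError):
    """A simulation target cannot be realized under the current configuration."""
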