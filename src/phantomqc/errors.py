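"""Exception types shared across the phantomqc pipeline."""


class PhantomQCError(Exception):
    """Base class for all phantomqc errors."""


class InvalidArgumentError(PhantomQCError, ValueError):
    """An argument violated an operation's contract."""


class NoPhantomDetectedError(PhantomQCError):
    """No region distinguishable from the background was found."""


class WaxNotFoundError(PhantomQCError):
    """The wax insert could not be located inside the phantom crop."""


class ConstantPatchError(PhantomQCError):
    """A patch with zero dynamic range cannot be rescaled to [0, 1]."""


class DegenerateTemplateError(PhantomQCError):
    """A noise template whose mean is zero cannot be intensity-scaled."""


class AlignmentFailedError(PhantomQCError):
    """Landmark-based alignment could not find usable landmarks."""


class ClassStarvedError(PhantomQCError):
    """A classification category has no training examples to balance from."""


class InvalidArchitectureError(PhantomQCError):
    """A network specification produces non-positive feature-map sizes."""


class DependencyError(PhantomQCError):
    """A pipeline stage was requested before its inputs exist."""
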