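"""Exception hierarchy shared across the package."""


class HerdfaceError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HerdfaceError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidStateError(HerdfaceError, RuntimeError):
    """An operation was invoked on an object in the wrong state."""


class DuplicateIdentityError(HerdfaceError, ValueError):
    """Enrolling an identity that is already present without merging."""


class IdentityNotFoundError(HerdfaceError, KeyError):
    """Referencing an identity absent from the gallery."""


class EmptyGalleryError(HerdfaceError, ValueError):
    """A lookup was attempted against a gallery with no records."""


class GalleryIOError(HerdfaceError, OSError):
    """Base class for gallery persistence failures."""


class GalleryNotFoundError(GalleryIOError):
    """The gallery directory or one of its files is missing."""


class GalleryVersionError(GalleryIOError):
    """The on-disk gallery uses an unsupported format version."""


class MalformedGalleryError(GalleryIOError):
    """The on-disk gallery files are inconsistent or unparseable."""


class ConfigError(HerdfaceError, ValueError):
    """A configuration value is out of its documented range."""
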