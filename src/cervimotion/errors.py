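"""Exception hierarchy shared across the package."""


class CervimotionError(Exception):
    """Base class for all package-specific errors."""


# -- annotation validation -------------------------------------------------

class MissingLandmark(CervimotionError):
    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing landmarks: {', '.join(self.missing)}")


class DuplicateLandmark(CervimotionError):
    pass


class NonFiniteLandmark(CervimotionError):
    pass


class NonPositiveSpacing(CervimotionError):
    pass


class OutOfBounds(CervimotionError):
    pass


class UnknownImageWidth(CervimotionError):
    pass


class AmbiguousFacing(CervimotionError):
    pass


# -- geometry --------------------------------------------------------------

class DegenerateVertebra(CervimotionError):
    pass


# -- synthetic spine -------------------------------------------------------

class NegativeSD(CervimotionError):
    pass


class OutOfFrame(CervimotionError):
    pass


class InvalidSplit(CervimotionError):
    pass


# -- detector --------------------------------------------------------------

class EmptyImage(CervimotionError):
    pass


class EmptyDataset(CervimotionError):
    pass


class NonFiniteLoss(CervimotionError):
    pass


# -- metrics ---------------------------------------------------------------

class MismatchedLandmarks(CervimotionError):
    pass


class SpacingMismatch(CervimotionError):
    pass


class LengthMismatch(CervimotionError):
    pass


class InvalidN(CervimotionError):
    pass


# -- io / cli --------------------------------------------------------------

class ParseError(CervimotionError):
    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CaseMismatch(CervimotionError):
    pass


class InvalidConfig(CervimotionError):
    pass
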