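"""Exception hierarchy for the msnet pipeline."""


class MsnetError(Exception):
    """Base class for all msnet-specific errors."""


# --- preprocessing ---------------------------------------------------------

class DegenerateRange(MsnetError):
    """Histogram stretching is undefined for a constant image (max == min)."""


class EmptySource(MsnetError):
    """A dataset source (MS or HC collection, or a training set) is empty."""


class InsufficientSamples(MsnetError):
    """A hold-out spec requests more images of a class than are available."""


# --- augmentation ----------------------------------------------------------

class NonPositiveFactor(MsnetError):
    """Rescaling requires a strictly positive zoom factor."""


class NegativeVariance(MsnetError):
    """Gaussian noise injection requires a non-negative variance."""


class NonPositiveGamma(MsnetError):
    """Gamma correction requires a strictly positive exponent."""


# --- layer mathematics -----------------------------------------------------

class NonPositiveOutput(MsnetError):
    """A convolution output dimension evaluated to less than one pixel."""


class ChannelMismatch(MsnetError):
    """Filter channel depth does not match the input channel depth."""


class BatchTooSmall(MsnetError):
    """Batch normalization in train mode needs at least two samples."""


class NegativeActivation(MsnetError):
    """Stochastic pooling requires non-negative (post-ReLU) activations."""


class DimensionMismatch(MsnetError):
    """Fully-connected forward received incompatible shapes."""


class ShapeMismatch(MsnetError):
    """Input images do not match the network's configured input size."""


class InconsistentChaining(MsnetError):
    """A layer's input channels do not equal the previous layer's output."""


# --- training / evaluation -------------------------------------------------

class EmptyTrainingSet(MsnetError):
    """Training requires a non-empty training set."""


class SingleClassTrainingSet(MsnetError):
    """Training requires both classes to be present."""


class EmptyTestSet(MsnetError):
    """Evaluation requires a non-empty test set."""


class UndefinedMetric(MsnetError):
    """A confusion-matrix metric has a zero denominator."""


# --- statistics ------------------------------------------------------------

class LengthMismatch(MsnetError):
    """Paired samples must have equal length."""


class TooLarge(MsnetError):
    """Exact signed-rank enumeration is limited to small sample sizes."""


# --- synthetic data --------------------------------------------------------

class InvalidParams(MsnetError):
    """Synthetic phantom parameters are out of their valid range."""
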