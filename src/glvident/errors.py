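"""Exception hierarchy for glvident."""


class GLVError(Exception):
    """Base class for all glvident errors."""


class DimensionError(GLVError, ValueError):
    """Input arrays have inconsistent shapes."""


class UndefinedCarryingCapacityError(GLVError, ZeroDivisionError):
    """Carrying capacity K_i = -r_i / B[i, i] is undefined for some species.

    Attributes
    ----------
    species : tuple of int
        Zero-based indices of the species with vanishing self-interaction.
    """

    def __init__(self, species):
        self.species = tuple(species)
        super().__init__(
            f"carrying capacity undefined (B[i,i] == 0) for species {self.species}"
        )


class IntegrationError(GLVError, RuntimeError):
    """ODE/SDE integration failed.

    Attributes
    ----------
    last_good_time : float
        The last time up to which the solution was computed successfully.
    """

    def __init__(self, message, last_good_time):
        self.last_good_time = last_good_time
        super().__init__(f"{message} (last good time: {last_good_time})")


class DegenerateSampleError(GLVError, ValueError):
    """A sample (row) has zero total abundance and cannot be normalized."""


class SingularReconstructionError(GLVError, ValueError):
    """Total-abundance reconstruction denominator vanishes at some times.

    Attributes
    ----------
    times : tuple of float
        Times at which the denominator is within tolerance of zero.
    """

    def __init__(self, times):
        self.times = tuple(float(t) for t in times)
        super().__init__(
            f"reconstruction denominator vanishes at times {self.times}"
        )


class DegenerateParametrizationError(GLVError, ValueError):
    """The leading coefficient of the input-output relation vanishes at the
    supplied parameter point, so the monic normalization is undefined there."""


class DerivationError(GLVError, RuntimeError):
    """Symbolic elimination failed to produce the input-output relation."""
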