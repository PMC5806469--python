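"""Named failure modes.

Validation problems raise at load time; degenerate algebra raises on direct
calls but is counted as a rejection inside Monte-Carlo sampling.
"""


class LignfluxError(Exception):
    """Base class for all package errors."""


class NetworkValidationError(LignfluxError):
    """A pathway config violates the schema or a structural invariant."""


class SchemaError(NetworkValidationError):
    """Config text does not conform to the documented JSON schema."""


class DuplicateIdError(NetworkValidationError):
    """A metabolite or flux id occurs more than once."""


class DiffusionPairError(NetworkValidationError):
    """A diffusion edge does not join a cytosol and an ER pool of one species."""


class CyclicNetworkError(NetworkValidationError):
    """The net-flux graph contains a directed cycle."""


class RoleError(NetworkValidationError):
    """A sink/wall/input role is missing, duplicated, or misassigned."""


class FSRMismatchError(LignfluxError):
    """An FSR vector does not cover exactly the network's branch points."""


class DegenerateTopologyError(LignfluxError):
    """A label-balance denominator vanishes (e.g. V2 = V1 + V3)."""


class DegenerateLabelError(LignfluxError):
    """Pool labels coincide (L4 = L2) so the exchange flux is unidentifiable."""


class InfeasibleLabelError(LignfluxError):
    """A computed label left [0, 1] or a diffusion component went negative.

    Inside Monte-Carlo sampling the same condition is a counted rejection,
    not an exception.
    """


class EmptyEnsembleError(LignfluxError):
    """An operation that needs ensemble members received none."""
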