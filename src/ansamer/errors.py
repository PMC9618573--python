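"""Exception hierarchy.

Exit codes used by the command-line layer:
2 = input/parse problem, 3 = topology problem (not a bridged macrolactam),
4 = geometric ambiguity/degeneracy.
"""


class AnsamerError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(AnsamerError):
    """Unreadable or empty input."""

    exit_code = 2


class FormatError(InputError):
    """Input violates the declared file-format dialect."""

    exit_code = 2


class TopologyError(AnsamerError):
    """Molecular graph does not match the expected bridged-macrolactam shape."""

    exit_code = 3


class NotMacrolactamError(TopologyError):
    """No head-to-tail backbone cycle was found."""


class MonocycleError(TopologyError):
    """Main cycle present but no bridge: the ansamer descriptor is undefined."""


class MultiBridgeError(TopologyError):
    """More than one independent cross-link; outside the supported topology."""


class AmbiguousCycleError(TopologyError):
    """Several distinct equally valid main-cycle candidates."""


class GeometryError(AnsamerError):
    exit_code = 4


class DegenerateGeometryError(GeometryError):
    """Point set too degenerate for a plane fit (e.g. collinear)."""


class AmbiguousGeometryError(GeometryError):
    """Leading atom lies in the mean plane; bridge side undecidable."""


class MassError(AnsamerError):
    """Unknown residue, element or invalid charge in mass bookkeeping."""

    exit_code = 2
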