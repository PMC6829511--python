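"""Exception hierarchy for mempsn."""


class MempsnError(Exception):
    """Base class for all package errors."""


class FormatError(MempsnError):
    """A structure or trajectory file could not be parsed."""


class UnknownResidueError(MempsnError):
    """Residue names absent from the role map."""

    def __init__(self, names):
        self.names = sorted(set(names))
        super().__init__(
            "residue name(s) not in role map: " + ", ".join(self.names)
        )


class TopologyMismatchError(MempsnError):
    """Trajectory atom count does not match the topology."""


class EmptyTrajectoryError(MempsnError):
    """A trajectory with zero frames was supplied."""


class NoMembraneError(MempsnError):
    """Leaflet assignment requested on a system without lipids."""


class NoHydrogensError(MempsnError):
    """H-bond detection requested but the system carries no hydrogen atoms."""


class ThresholdUndefinedError(MempsnError):
    """Largest-cluster-size curve is degenerate; supply p_T manually."""


class UnknownNodeError(MempsnError):
    """Node key(s) absent from the network."""

    def __init__(self, names):
        self.names = sorted(set(names))
        super().__init__("unknown node(s): " + ", ".join(self.names))


class MissingRadiusError(MempsnError):
    """An atom needed for SASA has no van der Waals radius."""


class MissingChargeError(MempsnError):
    """Partial charges required but absent (and no fallback enabled)."""


class ConfigError(MempsnError):
    """Invalid generator or pipeline configuration."""
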