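"""Exception hierarchy shared across the toolkit."""


class KinmodError(Exception):
    """Base class for all toolkit errors."""


class NameCollisionError(KinmodError):
    """A component name is already registered on the model."""


class UnknownSymbolError(KinmodError):
    """A rate argument or stoichiometry key does not resolve to any component."""


class ReservedNameError(KinmodError):
    """A component tried to use a reserved token such as ``time``."""


class CycleError(KinmodError):
    """The derived-parameter dependency graph contains a cycle."""


class EmptyModelError(KinmodError):
    """An operation requires at least one compound and one reaction."""


class ParameterDomainError(KinmodError, ValueError):
    """A kinetic parameter is outside its admissible domain (e.g. Km <= 0)."""


class IntegrationError(KinmodError):
    """The ODE solver failed; the message carries the solver diagnostic."""


class NonConvergenceError(KinmodError):
    """Steady-state search exhausted its integration horizon without converging."""


class StationarityError(KinmodError):
    """Fluxes handed to a linear label model do not balance at some pool."""


class LabelMappingError(KinmodError):
    """An atom transition map is inconsistent with the base model."""


class SbmlExportError(KinmodError):
    """The model contains a construct that cannot be serialised to SBML."""


class UnsupportedConstructError(KinmodError):
    """An SBML document uses constructs outside the supported subset."""

    def __init__(self, constructs):
        self.constructs = list(constructs)
        super().__init__(
            "unsupported SBML constructs: " + ", ".join(self.constructs)
        )
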