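"""Exception hierarchy shared across the package.

User-facing errors (bad input, unresolvable names) derive from
:class:`OntosearchError`; the CLI maps them to exit code 1 and anything
else to exit code 2.
"""


class OntosearchError(Exception):
    """Base class for all user-facing errors raised by ontosearch."""


class FormatError(OntosearchError):
    """An RDF source could not be parsed."""


class ConnectivityError(OntosearchError):
    """A SPARQL endpoint could not be reached."""


class EmptyQueryError(OntosearchError):
    """The query text was empty or whitespace-only."""


class MalformedTagError(OntosearchError):
    """A token looked like a semantic tag but carried no valid name."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"malformed semantic tag: {token!r}")


class UnknownTermError(OntosearchError):
    """A class/property constraint did not resolve in the mediating ontology."""


class UnknownDatasetError(OntosearchError):
    """A dataset constraint named an unregistered dataset."""


class IncompatibleKindError(OntosearchError):
    """Similarity was requested between a class and a property."""


class UnknownFacetError(OntosearchError):
    """A facet leaf does not belong to the tree built from these results."""


class FederationError(OntosearchError):
    """Every dataset in the plan failed to execute."""


class FixtureSpecError(OntosearchError):
    """A fixture specification was internally inconsistent."""


class ConfigError(OntosearchError):
    """A configuration file contained unknown or invalid keys."""
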