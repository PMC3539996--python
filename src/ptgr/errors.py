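"""Exception hierarchy shared across the toolkit."""


class PtgrError(Exception):
    """Base class for all toolkit errors."""


class SequenceError(PtgrError, ValueError):
    """Invalid nucleotide text or molecule geometry."""


class DigestError(PtgrError):
    """Restriction digestion cannot proceed."""


class UncutPlasmid(DigestError):
    """Signal: a circular molecule carries no site for the given enzymes.

    Distinct from a hard error -- callers that can tolerate an intact
    plasmid may catch this specifically.
    """


class SiteCollisionError(DigestError):
    """Two cut sites overlap so closely that the overhangs collide."""


class LigationError(PtgrError):
    """Ligation request is malformed (incompatible ends, bad fragment set)."""


class GrammarError(PtgrError):
    """A part or plasmid violates the pTGR slot grammar."""


class AssemblyError(PtgrError):
    """A cloning procedure or plan cannot be executed."""


class GeneDesignError(PtgrError):
    """Codon recoding cannot satisfy the forbidden-site constraints."""


class RegistryError(PtgrError):
    """Part registry file or entry is malformed."""


class RegulatorRequiredWarning(UserWarning):
    """An inducible promoter was installed without its cognate regulator."""
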