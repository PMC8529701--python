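"""Exception hierarchy shared across the package."""


class PhytofoundryError(Exception):
    """Base class for all package errors."""


# --- registry -------------------------------------------------------------

class RegistrySchemaError(PhytofoundryError):
    """A required column/key is missing or a file is empty/unparseable."""


class DuplicatePartError(PhytofoundryError):
    """Two registry records share a part_id."""


class FusionSiteGrammarError(PhytofoundryError):
    """A fusion site does not match [ACGT]{4} or violates the category grammar."""


class UnknownCategoryError(PhytofoundryError):
    """A part carries a category outside the controlled vocabulary."""


class SequenceUnavailableError(PhytofoundryError):
    """An operation needs a part sequence that is absent from the registry."""


class SequenceFormatError(PhytofoundryError):
    """A sequence file could not be parsed in the named format."""


class SequenceContentError(PhytofoundryError):
    """A sequence file parsed but holds no usable record."""


# --- goldengate -----------------------------------------------------------

class UndigestibleError(PhytofoundryError):
    """The molecule carries no cut site of the digesting enzyme."""


class CutGeometryError(PhytofoundryError):
    """Cut sites overlap or are otherwise inconsistent with clean excision."""


class IncompleteCycleError(PhytofoundryError):
    """No circular product closes; carries the missing junction."""

    def __init__(self, message, missing_junction=None):
        super().__init__(message)
        self.missing_junction = missing_junction


class AmbiguousAssemblyError(PhytofoundryError):
    """More than one distinct circular product satisfies the overhang chain."""


class DomesticationError(PhytofoundryError):
    """A part body contains an internal recognition site of the assembly enzyme."""


# --- designer -------------------------------------------------------------

class UnresolvedPartError(PhytofoundryError):
    """A design references a part_id absent from the registry."""


class FrameError(PhytofoundryError):
    """No translation start found at the expected junction."""


class PrematureStopError(PhytofoundryError):
    """An in-frame stop codon occurs before the C-tag-supplied stop."""

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class UnknownProteaseError(PhytofoundryError):
    """Protease name outside the supported set."""


# --- foundry --------------------------------------------------------------

class SourceTooDiluteError(PhytofoundryError):
    """Required plasmid volume exceeds the sample (cherry-pick) volume."""


class PlateCapacityError(PhytofoundryError):
    """More destination wells requested than the plate geometry allows."""


class PicklistError(PhytofoundryError):
    """Invalid picklist content (e.g. empty picklist on write)."""


# --- quant ----------------------------------------------------------------

class StandardCurveError(PhytofoundryError):
    """Standard-curve fitting failed or the curve is unusable."""


class ReplicateAlignmentError(PhytofoundryError):
    """Soluble and total replicate vectors have mismatched lengths."""


# --- assay ----------------------------------------------------------------

class ChemistryError(PhytofoundryError):
    """Formula arithmetic violated (missing condensation partner, negative counts)."""


class UnknownAdductError(PhytofoundryError):
    """Adduct name outside the supported set."""


class AlphabetError(PhytofoundryError):
    """A DNA string contains characters outside A/C/G/T."""


# --- shared ---------------------------------------------------------------

class DomainError(PhytofoundryError):
    """A numeric input is outside its valid domain (e.g. nonpositive mass)."""


class FixtureGenerationError(PhytofoundryError):
    """Bounded retries exhausted while generating a domesticated sequence."""
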