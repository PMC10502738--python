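"""Exception hierarchy for the camp package."""


class CampError(Exception):
    """Base class for all camp-specific errors."""


# --- genotype handling ---------------------------------------------------


class AllMarkersMonomorphic(CampError):
    """No marker survived the variance / MAF filter."""


class MonomorphicMarker(CampError):
    """A single marker offered for fitting carries no variation."""


# --- model fitting -------------------------------------------------------


class NoEvents(CampError):
    """A survival fit was requested on a cohort without any observed event."""


class NotConverged(CampError):
    """An operation that requires a converged fit received one that is not."""


class NonConvergence(CampError):
    """An iterative optimizer exhausted its budget without converging."""


# --- age-testing framework -----------------------------------------------


class InvalidCovariance(CampError):
    """The (beta0, beta1) covariance block is not positive semidefinite."""


class DegenerateFit(CampError):
    """beta0 = beta1 = 0 exactly; the chi-squared trajectory is identically 0."""


class NegativeStatistic(CampError):
    """A chi-squared statistic below zero was passed to a p-value routine."""


# --- simulation ----------------------------------------------------------


class NonFiniteHazard(CampError):
    """The cumulative hazard overflowed (effect sizes too large)."""


# --- LOCO / clumping -----------------------------------------------------


class UnknownChromosome(CampError):
    """A chromosome absent from the fitted model was requested."""


class UnknownMarker(CampError):
    """A marker id absent from the genotype panel was requested."""


# --- file I/O ------------------------------------------------------------


class BadMagic(CampError):
    """A PLINK .bed file does not start with the SNP-major magic bytes."""


class TruncatedFile(CampError):
    """A binary genotype file is shorter than its dimensions require."""


class DimensionMismatch(CampError):
    """.bed/.bim/.fam dimensions disagree."""


class MissingColumn(CampError):
    """A required column is absent from a tabular input."""


class NonNumericAge(CampError):
    """The age column of a phenotype table could not be parsed as numbers."""


class IOFailure(CampError):
    """A read or write of a camp-produced file failed."""
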