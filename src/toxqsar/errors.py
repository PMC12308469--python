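"""Exception hierarchy shared across the package."""


class ToxQsarError(Exception):
    """Base class for all toxqsar errors."""


class SchemaError(ToxQsarError):
    """Input table does not match the expected schema (missing columns, bad labels, empty)."""


class SmilesError(ToxQsarError):
    """A SMILES string could not be parsed into a valid molecule."""


class RegistryError(ToxQsarError):
    """An unknown descriptor set, algorithm or endpoint name was requested."""


class AlignmentError(ToxQsarError):
    """Feature names of a matrix do not match what a model or normalizer expects."""


class BundleError(ToxQsarError):
    """A persisted model bundle is missing, corrupted or of an unknown format version."""
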