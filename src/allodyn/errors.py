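"""Exception hierarchy shared across the package."""


class AllodynError(Exception):
    """Base class for all package-specific errors."""


class StructureError(AllodynError):
    """Malformed or unusable structure/ensemble input."""


class SelectionError(AllodynError):
    """A selection expression is invalid or resolves to nothing."""


class AnalysisError(AllodynError):
    """An analysis precondition is violated (too few frames, bad arguments...)."""


class ConfigError(AllodynError):
    """A run configuration failed validation.

    Carries the full aggregated list of problems, never just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("configuration invalid:\n" + "\n".join(f"  - {p}" for p in self.problems))
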