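"""The fixed three-class vocabulary of the germination detector.

A radicle shorter than half the seed length is an ``S_root``; once it
reaches half the seed length the object becomes an ``L_root`` and the seed
counts as germinated.
"""

CLASS_NAMES: tuple[str, ...] = ("seed", "S_root", "L_root")
CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}


class VocabularyError(ValueError):
    """Raised for a class label outside the fixed vocabulary."""


def check_label(label: str) -> str:
    if label not in CLASS_INDEX:
        raise VocabularyError(f"unknown class {label!r}; expected one of {CLASS_NAMES}")
    return label
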