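"""Small rule-based English lemmatizer.

Dictionary of common irregular forms plus conservative suffix rules for
plural nouns and -ing/-ed verb forms. Tokens that look like biomedical
symbols (containing digits or underscores) are never touched, so gene
symbols such as "brca1" or normalized concepts such as "breast_neoplasms"
pass through unchanged.
"""

from __future__ import annotations

_VOWELS = set("aeiou")

# Irregular forms worth handling explicitly in abstracts.
_EXCEPTIONS = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "doing": "do",
    "mice": "mouse", "men": "man", "women": "woman", "children": "child",
    "feet": "foot", "teeth": "tooth", "geese": "goose", "people": "person",
    "analyses": "analysis", "hypotheses": "hypothesis", "theses": "thesis",
    "diagnoses": "diagnosis", "prognoses": "prognosis",
    "criteria": "criterion", "phenomena": "phenomenon",
    "bacteria": "bacterium", "mitochondria": "mitochondrion",
    "nuclei": "nucleus", "stimuli": "stimulus", "fungi": "fungus",
    "genera": "genus", "larvae": "larva",
    "found": "find", "shown": "show", "showed": "show", "gave": "give",
    "given": "give", "taken": "take", "took": "take", "made": "make",
    "said": "say", "seen": "see", "saw": "see", "known": "know",
    "grew": "grow", "grown": "grow", "led": "lead", "arose": "arise",
    "arisen": "arise", "became": "become", "underwent": "undergo",
    # mass/unchanged nouns that the -s/-a rules would mangle
    "data": "data", "species": "species", "series": "series",
    "this": "this", "thus": "thus", "its": "its", "has_": "has_",
}


def _has_vowel(word: str) -> bool:
    return any(c in _VOWELS for c in word)


def lemmatize(token: str) -> str:
    """Return the lemma of a single lowercase token."""
    if len(token) <= 2 or any(c.isdigit() for c in token) or "_" in token:
        return token
    if token in _EXCEPTIONS:
        return _EXCEPTIONS[token]

    # plural / 3rd person -s
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith(("ches", "shes", "xes", "zes")) and len(token) > 4:
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]

    # past tense -ed
    if token.endswith("ied") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("ed") and len(token) > 3:
        stem = token[:-2]
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]  # stopped -> stop
        if len(stem) < 3 or not _has_vowel(stem):
            return token[:-1]  # used -> use
        return stem

    # progressive -ing
    if token.endswith("ing") and len(token) > 5:
        stem = token[:-3]
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]  # running -> run
        if not _has_vowel(stem):
            return token
        return stem

    return token


def lemmatize_phrase(words: tuple[str, ...]) -> tuple[str, ...]:
    """Lemmatize each word of a phrase tuple."""
    return tuple(lemmatize(w) for w in words)
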