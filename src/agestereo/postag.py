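"""Rule-based content-word tagging and lemmatization.

Word counting needs nouns and adjectives, lemmatized and lowercased.  This
module implements a deterministic rule-based tagger: closed-class function
words (pronouns, determiners, prepositions, conjunctions, auxiliaries,
common light verbs), adverbs (``-ly`` forms outside a small adjectival
whitelist) and verbal ``-ing`` participles are excluded; every remaining
open-class token is treated as a noun/adjective content word.  The
lemmatizer strips regular plural suffixes only.

Rule-based tagging is coarser than a statistical tagger: gerunds and
participles are the main ambiguity (``running`` is excluded here unless
whitelisted as a noun/adjective), and counts can shift slightly against
statistical taggers on such forms.
"""

from __future__ import annotations

from .corpus import tokenize

__all__ = ["content_lemmas", "lemmatize", "is_content_word"]

_PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us",
    "them", "my", "your", "his", "its", "our", "their", "mine", "yours",
    "hers", "ours", "theirs", "myself", "yourself", "himself", "herself",
    "itself", "ourselves", "themselves", "who", "whom", "whose", "which",
    "what", "this", "that", "these", "those", "someone", "anyone",
    "everyone", "something", "anything", "everything", "nothing", "one",
}
_DETERMINERS = {
    "a", "an", "the", "some", "any", "no", "every", "each", "either",
    "neither", "both", "all", "many", "much", "few", "several", "most",
    "more", "less", "other", "another", "such", "own", "same",
}
_PREPOSITIONS = {
    "of", "in", "on", "at", "by", "for", "with", "about", "against",
    "between", "among", "into", "through", "during", "before", "after",
    "above", "below", "to", "from", "up", "down", "out", "off", "over",
    "under", "around", "toward", "towards", "upon", "within", "without",
    "across", "behind", "beyond", "near", "like", "as", "than", "per",
    "regardless", "despite", "throughout",
}
_CONJUNCTIONS = {
    "and", "or", "but", "nor", "so", "yet", "because", "although", "though",
    "while", "whether", "if", "unless", "since", "until", "when", "where",
    "whereas", "however", "therefore", "thus", "hence",
}
_AUX_AND_COMMON_VERBS = {
    "am", "is", "are", "was", "were", "be", "been", "being", "do", "does",
    "did", "done", "have", "has", "had", "having", "can", "could", "will",
    "would", "shall", "should", "may", "might", "must", "get", "gets",
    "got", "make", "makes", "made", "take", "takes", "took", "go", "goes",
    "went", "come", "comes", "came", "become", "becomes", "became", "seem",
    "seems", "seemed", "tend", "tends", "tended", "begin", "begins",
    "began", "start", "starts", "started", "keep", "keeps", "kept", "note",
    "mind", "hope", "hopes", "hoped", "want", "wants", "wanted", "find",
    "finds", "found", "show", "shows", "showed", "shown", "give", "gives",
    "gave", "given", "let", "lets", "say", "says", "said", "know", "knows",
    "knew", "known", "feel", "feels", "felt", "see", "sees", "saw", "seen",
    "display", "displays", "displayed", "exhibit", "exhibits", "exhibited",
    "vary", "varies", "varied", "depend", "depends", "depended",
}
_ADVERBS = {
    "not", "very", "too", "quite", "rather", "often", "sometimes", "usually",
    "always", "never", "rarely", "seldom", "also", "just", "still", "even",
    "again", "here", "there", "now", "then", "soon", "already", "almost",
    "perhaps", "maybe", "well", "instead", "alike", "away", "together",
    "alone", "else", "once", "twice", "far", "enough",
}
_NUMBERS = {
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten",
}
_MISC = {"it's", "there's", "that's", "yes", "sure", "okay", "oh", "etc"}

#: ``-ly`` words that are adjectives, not adverbs.
_LY_ADJECTIVES = {
    "friendly", "unfriendly", "lonely", "lively", "elderly", "lovely",
    "silly", "ugly", "early", "daily", "orderly", "costly", "likely",
    "unlikely",
}
#: ``-ing`` forms accepted as nouns/adjectives (gerund nouns, fixed adjectives).
_ING_CONTENT = {
    "outgoing", "caring", "understanding", "charming", "loving", "daring",
    "willing", "cunning", "feeling", "thing", "something", "everything",
    "anything", "nothing", "morning", "evening", "being", "wellbeing",
    "learning", "upbringing",
}

_STOPLIST = (
    _PRONOUNS
    | _DETERMINERS
    | _PREPOSITIONS
    | _CONJUNCTIONS
    | _AUX_AND_COMMON_VERBS
    | _ADVERBS
    | _NUMBERS
    | _MISC
)


def is_content_word(token: str) -> bool:
    """True if a (lowercased, punctuation-stripped) token is kept as noun/adjective."""
    if not token or any(ch.isdigit() for ch in token):
        return False
    if token in _STOPLIST:
        return False
    if token.endswith("ly") and token not in _LY_ADJECTIVES:
        return False
    if token.endswith("ing") and token not in _ING_CONTENT:
        return False
    return True


def lemmatize(token: str) -> str:
    """Strip regular plural suffixes (conservative; lemmas map to themselves)."""
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    for suffix in ("ses", "xes", "zes", "ches", "shes"):
        if len(token) > len(suffix) + 1 and token.endswith(suffix):
            return token[:-2]
    if (
        len(token) > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


def content_lemmas(text: str) -> list[str]:
    """Lowercased noun/adjective lemmas of ``text``, in order of occurrence."""
    return [lemmatize(t) for t in tokenize(text) if is_content_word(t)]
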