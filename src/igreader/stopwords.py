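"""Closed-class (functional) English words.

Determiners, prepositions, conjunctions, pronouns and auxiliaries — the
closed grammatical classes — ordered roughly by descending everyday
frequency so that synthetic corpora can reuse the head of the list as their
most frequent shared words.  Membership in this list is what classifies a
word as ``functional`` rather than ``content``.
"""

FUNCTIONAL_WORD_LIST: list[str] = [
    "the", "of", "and", "a", "to", "in", "is", "was", "that", "for",
    "it", "as", "with", "on", "be", "by", "at", "are", "this", "from",
    "or", "an", "not", "his", "but", "they", "which", "he", "had", "were",
    "their", "have", "has", "its", "been", "will", "would", "who", "she",
    "her", "we", "you", "all", "can", "there", "them", "him", "than",
    "into", "if", "no", "my", "your", "our", "these", "those", "what",
    "when", "where", "how", "why", "because", "while", "after", "before",
    "between", "during", "under", "over", "through", "about", "against",
    "above", "below", "up", "down", "out", "off", "again", "then", "once",
    "both", "each", "few", "more", "most", "other", "some", "such",
    "only", "own", "same", "so", "too", "very", "just", "also", "any",
    "could", "should", "may", "might", "must", "shall", "do", "does",
    "did", "am", "being", "i", "me", "us", "mine", "yours", "hers",
    "ours", "theirs", "itself", "himself", "herself", "themselves",
    "whom", "whose", "either", "neither", "nor", "yet", "although",
    "though", "unless", "until", "upon", "within", "without", "toward",
    "towards", "among", "amongst", "per", "via", "versus",
]

FUNCTIONAL_WORDS: frozenset[str] = frozenset(FUNCTIONAL_WORD_LIST)
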