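"""Deterministic rule-based linguistic backend for short informal posts.

The feature extractor needs four capabilities from a backend — tokenize,
lemmatize, coarse POS-tag, dependency-parse — behind the
:class:`ParserBackend` protocol.  The pinned default,
:class:`RuleBasedBackend`, is a small hand-written tagger/parser tuned to
the first/second/third-person constructions that dominate health-status
posts ("I have X", "my mom has X", "she is fighting X").  It is exact and
reproducible: a fixed input always yields the same parse, with no model
files and no download.

Coverage is intentionally shallow — closed-class word lists, a suffix
lemmatizer with an irregular table, and head-finding heuristics that emit
Stanford-style arcs (``nsubj``, ``dobj``, ``poss``, ``amod``, ``compound``,
collapsed ``prep_*``).  Feature strings are therefore backend-specific;
swapping in a statistical parser changes the dependency vocabulary but not
the extractor contract.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Protocol

__all__ = ["Token", "Arc", "ParserBackend", "RuleBasedBackend", "is_emoji"]


@dataclass(frozen=True)
class Token:
    text: str
    lemma: str
    pos: str  # NOUN VERB PRON ADJ ADV DET ADP CONJ AUX PART NUM PUNCT EMOJI
    i: int


@dataclass(frozen=True)
class Arc:
    relation: str
    head: Token
    dep: Token


class ParserBackend(Protocol):
    """Contract for a linguistic backend: deterministic for a fixed input."""

    name: str
    version: str

    def parse(self, text: str) -> tuple[list[Token], list[Arc]]: ...


# ---------------------------------------------------------------------------
# emoji detection (code-point ranges; no external package)

_EMOJI_RANGES = (
    (0x1F000, 0x1FAFF),  # mahjong .. symbols-extended
    (0x2600, 0x27BF),    # misc symbols, dingbats (hearts, crosses)
    (0x2B00, 0x2BFF),    # arrows/stars (⭐)
    (0xFE0F, 0xFE0F),    # variation selector kept with its base glyph
    (0x1F1E6, 0x1F1FF),  # regional indicators
)


def is_emoji(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _EMOJI_RANGES)


# ---------------------------------------------------------------------------
# closed word classes

_PRONOUNS = {
    "i", "me", "my", "mine", "myself",
    "we", "us", "our", "ours", "ourselves",
    "you", "your", "yours", "yourself",
    "he", "him", "his", "himself",
    "she", "her", "hers", "herself",
    "it", "its", "itself",
    "they", "them", "their", "theirs", "themselves",
    "who", "whom", "someone", "anyone", "everyone", "nobody", "somebody",
}
_POSSESSIVE_PRON = {"my", "your", "his", "her", "its", "our", "their"}
_DETERMINERS = {
    "the", "a", "an", "this", "that", "these", "those", "some", "any",
    "no", "every", "each", "another",
}
_ADPOSITIONS = {
    "of", "in", "on", "at", "by", "for", "with", "from", "to", "about",
    "after", "before", "over", "under", "into", "through", "against",
    "without", "like",
}
_CONJUNCTIONS = {"and", "or", "but", "so", "because", "if", "when", "while",
                 "than", "though", "although"}
_MODALS = {"will", "would", "can", "could", "shall", "should", "may",
           "might", "must", "wont", "cant", "gonna", "gotta"}
_PARTICLES = {"not", "nt", "n't", "too", "also"}
_ADVERBS = {
    "very", "so", "really", "just", "often", "never", "always", "now",
    "here", "there", "again", "soon", "only", "still", "even", "already",
    "today", "tomorrow", "yesterday", "maybe", "please",
}
_ADJECTIVES = {
    "good", "bad", "great", "little", "big", "free", "sick", "ill", "new",
    "old", "seasonal", "high", "low", "happy", "sad", "terrible", "awful",
    "strong", "brave", "rough", "pure", "chronic", "severe", "mild",
    "positive", "negative", "healthy", "lucky", "late", "last",
}
_INTERJECTIONS = {"lol", "lmao", "omg", "wow", "yay", "ugh", "oh", "hey",
                  "thanks", "ok", "okay", "yeah", "hmm"}

# verb base forms; inflections are reduced to these before lookup
_VERB_BASES = {
    "be", "have", "do", "make", "get", "go", "take", "give", "look",
    "suffer", "battle", "fight", "pray", "hope", "feel", "think", "say",
    "know", "see", "come", "want", "need", "love", "hate", "help",
    "worry", "diagnose", "survive", "beat", "die", "live", "struggle",
    "deal", "cope", "catch", "spread", "test", "wish", "miss", "lose",
    "win", "try", "start", "stop", "keep", "put", "tell", "ask", "work",
    "turn", "run", "eat", "sleep", "cry", "send", "find", "hear", "talk",
    "call", "wait", "stay", "leave", "read", "watch", "apply", "hire",
    "scream", "walk", "brighten", "appreciate", "support", "cure",
    "treat", "recover", "act", "seem", "mean", "happen", "end",
}

_IRREGULAR_VERBS = {
    "is": "be", "am": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be", "m": "be", "s": "be", "re": "be",
    "has": "have", "had": "have", "having": "have", "ve": "have",
    "does": "do", "did": "do", "done": "do", "doing": "do",
    "made": "make", "making": "make",
    "got": "get", "gotten": "get", "getting": "get",
    "went": "go", "gone": "go", "going": "go", "goes": "go",
    "took": "take", "taken": "take", "taking": "take",
    "gave": "give", "given": "give", "giving": "give",
    "felt": "feel", "thought": "think", "said": "say", "knew": "know",
    "known": "know", "saw": "see", "seen": "see", "came": "come",
    "beat": "beat", "died": "die", "dying": "die", "lost": "lose",
    "won": "win", "kept": "keep", "told": "tell", "heard": "hear",
    "found": "find", "sent": "send", "left": "leave", "ran": "run",
    "ate": "eat", "slept": "sleep", "caught": "catch",
}

_WORD_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)*|\d+|\S")


def _strip_inflection(word: str) -> list[str]:
    """Candidate base forms for a possibly inflected verb, best first."""
    cands = [word]
    if word.endswith("ies") and len(word) > 4:
        cands.append(word[:-3] + "y")
    if word.endswith("es") and len(word) > 3:
        cands.append(word[:-2])
    if word.endswith("s") and len(word) > 2 and not word.endswith("ss"):
        cands.append(word[:-1])
    if word.endswith("ing") and len(word) > 4:
        stem = word[:-3]
        cands += [stem, stem + "e"]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # battling? no: running
            cands.append(stem[:-1])
    if word.endswith("ed") and len(word) > 3:
        stem = word[:-2]
        cands += [stem, stem + "e" if not stem.endswith("e") else stem]
        cands.append(word[:-1])  # diagnosed -> diagnose
        if len(stem) > 2 and stem[-1] == stem[-2]:
            cands.append(stem[:-1])
    if word.endswith("ying") and len(word) > 5:
        cands.append(word[:-4] + "y")  # praying handled by -ing already
    return cands


def _noun_lemma(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "xes", "zes", "sses")):
        return word[:-2]
    if word.endswith("s") and len(word) > 3 and not word.endswith(
        ("ss", "us", "is")
    ):
        return word[:-1]
    return word


class RuleBasedBackend:
    """The package's pinned deterministic tagger/lemmatizer/parser."""

    name = "rule-based"
    version = "1.0"

    # -- tagging ------------------------------------------------------------

    def tokenize(self, text: str) -> list[str]:
        return _WORD_RE.findall(text)

    def _tag_word(self, low: str) -> tuple[str, str]:
        """(pos, lemma) for one lowercase word token."""
        if low in _PRONOUNS:
            return "PRON", low
        if low in _IRREGULAR_VERBS:
            return "VERB", _IRREGULAR_VERBS[low]
        if low in _VERB_BASES:
            return "VERB", low
        if low in _DETERMINERS:
            return "DET", low
        if low in _ADPOSITIONS:
            return "ADP", low
        if low in _CONJUNCTIONS:
            return "CONJ", low
        if low in _MODALS:
            return "AUX", low
        if low in _PARTICLES:
            return "PART", low
        if low in _INTERJECTIONS:
            return "INTJ", low
        if low in _ADJECTIVES or low.endswith(("less", "ful", "ish")):
            return "ADJ", low
        if low in _ADVERBS or (low.endswith("ly") and len(low) > 4):
            return "ADV", low
        for cand in _strip_inflection(low):
            if cand in _VERB_BASES:
                return "VERB", cand
        return "NOUN", _noun_lemma(low)

    def tag(self, text: str) -> list[Token]:
        tokens: list[Token] = []
        for i, raw in enumerate(self.tokenize(text)):
            if len(raw) == 1 and is_emoji(raw):
                tokens.append(Token(raw, raw, "EMOJI", i))
                continue
            if len(raw) == 1 and unicodedata.category(raw).startswith("P"):
                tokens.append(Token(raw, raw, "PUNCT", i))
                continue
            if raw.isdigit():
                tokens.append(Token(raw, raw, "NUM", i))
                continue
            low = raw.lower()
            if "'" in low:  # split off clitics: she's, don't, cancer's
                head, _, clitic = low.partition("'")
                pos, lemma = self._tag_word(head)
                tokens.append(Token(raw, lemma, pos, i))
                # the clitic itself ('s, 're, n't) carries no feature mass
                continue
            pos, lemma = self._tag_word(low)
            tokens.append(Token(raw, lemma, pos, i))
        return tokens

    # -- dependencies -------------------------------------------------------

    _CONTENT = {"NOUN", "PRON", "PROPN"}
    _SKIP_RIGHT = {"DET", "ADJ", "ADV", "PART", "AUX", "NUM"}
    _SKIP_LEFT = {"ADV", "AUX", "PART", "DET", "ADJ", "NUM"}

    def parse(self, text: str) -> tuple[list[Token], list[Arc]]:
        tokens = self.tag(text)
        arcs: list[Arc] = []
        n = len(tokens)

        def boundary(tok: Token) -> bool:
            return tok.pos in {"PUNCT", "CONJ", "EMOJI"}

        for j, tok in enumerate(tokens):
            if tok.pos == "VERB":
                # subject: nearest content word to the left
                for k in range(j - 1, -1, -1):
                    t = tokens[k]
                    if boundary(t) or t.pos == "VERB":
                        break
                    if t.pos in self._CONTENT:
                        arcs.append(Arc("nsubj", tok, t))
                        break
                    if t.pos not in self._SKIP_LEFT and t.pos != "ADP":
                        break
                # object / oblique: scan right; a pronoun object is
                # indirect ("give him a X"), so keep looking for the noun
                k = j + 1
                prep: Token | None = None
                while k < n:
                    t = tokens[k]
                    if boundary(t) or t.pos == "VERB":
                        break
                    if t.pos == "ADP":
                        prep = t
                        k += 1
                        continue
                    if t.pos in self._CONTENT:
                        if prep is not None:
                            arcs.append(Arc(f"prep_{prep.lemma}", tok, t))
                            break
                        if t.pos == "PRON":
                            arcs.append(Arc("iobj", tok, t))
                            k += 1
                            continue
                        arcs.append(Arc("dobj", tok, t))
                        break
                    if t.pos not in self._SKIP_RIGHT:
                        break
                    k += 1
            elif tok.pos == "NOUN":
                if j > 0:
                    prev = tokens[j - 1]
                    if prev.pos == "PRON" and prev.lemma in _POSSESSIVE_PRON:
                        arcs.append(Arc("poss", tok, prev))
                    elif prev.pos == "ADJ":
                        arcs.append(Arc("amod", tok, prev))
                    elif prev.pos == "NOUN":
                        arcs.append(Arc("compound", tok, prev))
        return tokens, arcs
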