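"""Seeded synthetic corpora with planted co-occurrence structure.

The generator emulates the statistical skeleton of an abstract database:
each concept appears in a document with a base rate, planted pairs add
joint co-mentions, and planted hidden A–B–C structures add A–B and B–C
co-mentions while guaranteeing that A and C are never co-mentioned before
an assertion date (or at all).  Documents are rendered as filler text with
literal keyword tokens embedded under the tagger's boundary contract, so
the realized document→concept design matrix is exact ground truth for the
whole pipeline.

No linguistic realism is attempted: keywords are unambiguous nonsense
tokens disjoint from the filler vocabulary and the English-filter
dictionary (checked at generation time).  A dedicated fixture plants
ambiguous gene symbols for targeted disambiguation tests.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass

import numpy as np

from .corpus_io import Concept, ConfigError, Corpus, DocumentRecord, PubDate
from .tagger import MentionIndex
from .thesaurus_prep import load_dictionary

#: Fixed filler vocabulary; disjoint from every generated keyword and from
#: the shipped English word list (asserted at generation time).
FILLER_WORDS = (
    "voriv", "lemnor", "tasperil", "ondrevic", "shalmette", "quorandel",
    "brevitan", "moskelli", "fandrossi", "welkinore", "drosvane", "pelliturn",
    "garnovex", "hulverin", "satremol", "quennivar", "torvalenz", "miskarode",
    "abrelling", "chervonal", "dulcimbre", "efframine", "glavorren", "hysperol",
    "invarrock", "jorvalese", "kresandil", "lunovette", "morrandiv", "nulterway",
    "ostrephan", "pruvindel", "ravvenoir", "selcourin", "trebanthe", "ulvermont",
)


@dataclass(frozen=True)
class ConceptSpec:
    """One synthetic concept and its per-document occurrence probability."""

    concept_id: str
    category: str
    base_rate: float


@dataclass(frozen=True)
class PlantedPair:
    """A direct co-occurrence planted at ``joint_rate`` per document."""

    a: str
    b: str
    joint_rate: float


@dataclass(frozen=True)
class PlantedHidden:
    """A hidden A–C structure.

    ``intermediates`` lists B concepts whose A–B and B–C links are planted
    at ``link_rate`` per document and side.  With ``pre_split_only`` no
    document dated before ``assert_after`` ever co-mentions A and C (never,
    if ``assert_after`` is None); from ``assert_after`` on, direct A–C
    co-mentions are planted at ``assert_rate``.
    """

    a: str
    c: str
    intermediates: tuple[str, ...] = ()
    pre_split_only: bool = True
    assert_after: dt.date | None = None
    link_rate: float = 0.0
    assert_rate: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_docs: int
    year_range: tuple[float, float]
    concepts: tuple[ConceptSpec, ...]
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_hidden: tuple[PlantedHidden, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ConfigError("n_docs must be >= 1")
        lo, hi = self.year_range
        if not lo < hi:
            raise ConfigError("year_range must be increasing")
        rates = {c.concept_id: c.base_rate for c in self.concepts}
        for c in self.concepts:
            if not 0.0 < c.base_rate < 1.0:
                raise ConfigError(f"base_rate of {c.concept_id!r} outside (0,1)")
        for p in self.planted_pairs:
            if p.a not in rates or p.b not in rates:
                raise ConfigError(f"planted pair references unknown concept: {p}")
            if not 0.0 < p.joint_rate < 1.0:
                raise ConfigError(f"joint_rate outside (0,1): {p}")
            if p.joint_rate > min(rates[p.a], rates[p.b]):
                raise ConfigError(
                    f"joint_rate {p.joint_rate} exceeds member base rates for "
                    f"({p.a}, {p.b})"
                )
        for h in self.planted_hidden:
            if h.a not in rates or h.c not in rates:
                raise ConfigError(f"planted hidden references unknown concept: {h}")
            for b in h.intermediates:
                if b not in rates:
                    raise ConfigError(f"unknown intermediate {b!r} in {h}")
            if h.intermediates and not 0.0 < h.link_rate < 1.0:
                raise ConfigError(f"link_rate outside (0,1): {h}")
            if h.assert_after is not None and not 0.0 <= h.assert_rate < 1.0:
                raise ConfigError(f"assert_rate outside [0,1): {h}")


def _keyword_for(concept_id: str) -> str:
    # unique lowercase token; never a filler word or a dictionary word
    return f"zq{concept_id.lower()}ix"


def _date_from_float(x: float) -> PubDate:
    year = int(x)
    start = dt.date(year, 1, 1).toordinal()
    length = dt.date(year + 1, 1, 1).toordinal() - start
    d = dt.date.fromordinal(start + min(int((x - year) * length), length - 1))
    return PubDate(d.year, d.month, d.day)


@dataclass(frozen=True)
class SyntheticResult:
    """Generated corpus plus the realized (exact) ground truth."""

    config: SyntheticConfig
    corpus: Corpus
    thesaurus: tuple[Concept, ...]
    memberships: dict[str, frozenset[str]]

    @property
    def categories(self) -> dict[str, str]:
        return {c.concept_id: c.category for c in self.config.concepts}


def _check_vocabulary(cfg: SyntheticConfig) -> None:
    dictionary = load_dictionary()
    filler = {w.upper() for w in FILLER_WORDS}
    if filler & dictionary:
        raise ConfigError("filler vocabulary overlaps the English dictionary")
    for c in cfg.concepts:
        kw = _keyword_for(c.concept_id).upper()
        if kw in filler or kw in dictionary:
            raise ConfigError(f"keyword for {c.concept_id!r} collides with vocabulary")


def generate_corpus(cfg: SyntheticConfig) -> SyntheticResult:
    """Generate a corpus, thesaurus and exact ground truth from a config.

    The same seed yields byte-identical output.  Ground truth is the
    realized membership matrix (which concepts actually landed in which
    document), not the expected rates.
    """
    cfg.validate()
    _check_vocabulary(cfg)
    rng = np.random.default_rng(cfg.seed)
    concept_ids = [c.concept_id for c in cfg.concepts]
    lo, hi = cfg.year_range

    # Planted joint events live inside a concept's base rate: the residual
    # solo rate is base minus the concept's total planted rate (clipped at
    # zero), so the realized marginal tracks base_rate instead of inflating
    # with every planted link.  A concept whose links sum to its base rate
    # is a "specialist" that only ever appears alongside its partners.
    planted_total: dict[str, float] = {cid: 0.0 for cid in concept_ids}
    for p in cfg.planted_pairs:
        planted_total[p.a] += p.joint_rate
        planted_total[p.b] += p.joint_rate
    for h in cfg.planted_hidden:
        for b in h.intermediates:
            planted_total[h.a] += h.link_rate
            planted_total[b] += 2 * h.link_rate
            planted_total[h.c] += h.link_rate
        if h.assert_after is not None:
            planted_total[h.a] += h.assert_rate
            planted_total[h.c] += h.assert_rate
    residual = {
        c.concept_id: max(0.0, c.base_rate - planted_total[c.concept_id])
        for c in cfg.concepts
    }

    # documents are generated in date order for readability of the output
    dates = np.sort(rng.uniform(lo, hi, size=cfg.n_docs))

    records: list[DocumentRecord] = []
    memberships: dict[str, frozenset[str]] = {}
    width = max(4, len(str(cfg.n_docs)))
    for i in range(cfg.n_docs):
        doc_id = f"D{i + 1:0{width}d}"
        pub = _date_from_float(float(dates[i]))
        doc_date = pub.as_date()

        # planted events first; concepts they add are tallied so that the
        # hiddenness pass below prefers sacrificing incidental mentions
        evented: dict[str, int] = {}

        def _event(*cids: str) -> None:
            for cid in cids:
                evented[cid] = evented.get(cid, 0) + 1

        for p in cfg.planted_pairs:
            if rng.random() < p.joint_rate:
                _event(p.a, p.b)
        for h in cfg.planted_hidden:
            for b in h.intermediates:
                if rng.random() < h.link_rate:
                    _event(h.a, b)
                if rng.random() < h.link_rate:
                    _event(b, h.c)
        protected: set[str] = set()
        for h in cfg.planted_hidden:
            if h.assert_after is not None and doc_date >= h.assert_after:
                if rng.random() < h.assert_rate:
                    _event(h.a, h.c)
                    protected.update((h.a, h.c))

        present: set[str] = set(evented)
        draws = rng.random(len(concept_ids))
        for cid, u in zip(concept_ids, draws):
            if u < residual[cid]:
                present.add(cid)

        # enforce hiddenness: iterate to a fixpoint since removing one
        # concept can only shrink the membership set
        changed = True
        while changed:
            changed = False
            for h in cfg.planted_hidden:
                if not h.pre_split_only:
                    continue
                forbidden = h.assert_after is None or doc_date < h.assert_after
                if forbidden and h.a in present and h.c in present:
                    candidates = [x for x in (h.c, h.a) if x not in protected]
                    if not candidates:
                        candidates = [h.c]  # colliding assertions: drop c
                    if len(candidates) == 2:
                        # drop the member whose removal destroys the fewest
                        # planted co-mentions; break ties with a stable
                        # checksum so the loss splits evenly between sides
                        ca, cb = candidates
                        na, nb = evented.get(ca, 0), evented.get(cb, 0)
                        if na != nb:
                            victim = ca if na < nb else cb
                        else:
                            key = zlib.crc32(f"{h.a}|{h.c}|{doc_id}".encode())
                            victim = candidates[key & 1]
                    else:
                        victim = candidates[0]
                    present.discard(victim)
                    changed = True

        body_tokens: list[str] = list(
            rng.choice(FILLER_WORDS, size=6, replace=True)
        )
        for cid in sorted(present):
            body_tokens.append(_keyword_for(cid))
            body_tokens.append(str(rng.choice(FILLER_WORDS)))
        title = " ".join(rng.choice(FILLER_WORDS, size=3, replace=True))
        records.append(
            DocumentRecord(
                doc_id=doc_id,
                title=title,
                body=" ".join(body_tokens),
                substances=(),
                pub_date=pub,
            )
        )
        memberships[doc_id] = frozenset(present)

    thesaurus = tuple(
        Concept(c.concept_id, c.category, ((_keyword_for(c.concept_id), "full_name"),))
        for c in cfg.concepts
    )
    return SyntheticResult(
        config=cfg,
        corpus=Corpus(tuple(records)),
        thesaurus=thesaurus,
        memberships=memberships,
    )


def make_gold_concordance(result: SyntheticResult) -> MentionIndex:
    """The planted-truth mention index for end-to-end tagger comparison."""
    dates = {rec.doc_id: rec.pub_date for rec in result.corpus}
    return MentionIndex.from_doc_concepts(result.memberships, dates)


# ---------------------------------------------------------------------------
# Benchmark scenario for the literature-partitioning evaluation

BENCHMARK_SPLIT_DATE = dt.date(2000, 1, 1)
BENCHMARK_TEST_END = dt.date(2007, 5, 1)


def validation_benchmark(
    seed: int,
    n_docs: int = 2000,
    n_a: int = 14,
    n_c: int = 14,
    n_hubs: int = 6,
    n_true: int = 20,
    endpoint_base: float = 0.07,
    hub_link_rate: float = 0.007,
    dedicated_link_rate: float = 0.008,
    assert_rate: float = 0.008,
    n_legacy_pairs: int = 2,
    legacy_base: float = 0.5,
    legacy_overlap_start: dt.date = dt.date(1999, 1, 1),
) -> tuple[SyntheticConfig, list[tuple[str, str]]]:
    """Benchmark config for the time-sliced discovery evaluation.

    Structure (60 concepts at the defaults): ``n_a`` disease endpoints and
    ``n_c`` gene endpoints that are never co-mentioned before the split
    date; ``n_hubs`` promiscuous biological-process intermediates linked to
    every endpoint, giving every A–C pair the shared-intermediate
    background that makes it a candidate; dedicated intermediates (the
    remaining concept budget) dealt round-robin over the planted true pairs;
    and ``2 * n_legacy_pairs`` high-frequency generic terms forming
    scale-calibration pairs whose co-mention only emerges late in the
    background era.
    A dedicated intermediate is a specialist: its base rate equals the sum
    of its two link rates, so it appears only alongside its pair — the
    exclusivity the mutual-information score rewards (a promiscuous hub
    scores near or below chance, an exclusive bridge scores far above it).
    True pairs are asserted after the split date; every other A–C pair
    never co-occurs.  Returns the config and the list of true pairs.
    """
    if n_true > n_a * n_c:
        raise ConfigError("more true pairs than endpoint pairs")
    n_ded = 60 - n_a - n_c - n_hubs - 2 * n_legacy_pairs
    if n_ded < 1:
        raise ConfigError("no concept budget left for dedicated intermediates")
    a_ids = [f"a{i + 1:02d}" for i in range(n_a)]
    c_ids = [f"c{i + 1:02d}" for i in range(n_c)]
    hub_ids = [f"hub{i + 1:02d}" for i in range(n_hubs)]
    ded_ids = [f"ded{i + 1:02d}" for i in range(n_ded)]
    legacy_ids = [f"leg{i + 1:02d}" for i in range(2 * n_legacy_pairs)]

    # true pairs: the diagonal first, then shifted pairings — deterministic
    true_pairs: list[tuple[str, str]] = []
    shift = 0
    while len(true_pairs) < n_true:
        for i in range(n_a):
            if len(true_pairs) >= n_true:
                break
            pair = (a_ids[i], c_ids[(i + shift) % n_c])
            if pair not in true_pairs:
                true_pairs.append(pair)
        shift += n_c // 2 or 1

    # hub links: every endpoint to every hub
    links: dict[tuple[str, str], float] = {}
    for e in a_ids + c_ids:
        for h in hub_ids:
            links[(e, h)] = hub_link_rate
    # dedicated intermediates dealt round-robin over the true pairs
    for k, d in enumerate(ded_ids):
        a, c = true_pairs[k % n_true]
        links[(a, d)] = dedicated_link_rate
        links[(c, d)] = dedicated_link_rate
    planted_pairs = tuple(PlantedPair(x, y, rate) for (x, y), rate in links.items())

    # specialists carry exactly their link mass; endpoints keep a solo
    # residual on top of their links (diseases are discussed on their own)
    link_mass: dict[str, float] = {}
    for (x, y), rate in links.items():
        link_mass[x] = link_mass.get(x, 0.0) + rate
        link_mass[y] = link_mass.get(y, 0.0) + rate
    concepts = (
        [ConceptSpec(a, "disease", endpoint_base) for a in a_ids]
        + [ConceptSpec(c, "gene", endpoint_base) for c in c_ids]
        + [ConceptSpec(h, "biological_process", link_mass[h]) for h in hub_ids]
        + [ConceptSpec(d, "biological_process", link_mass[d]) for d in ded_ids]
        + [ConceptSpec(l, "liver_pathology", legacy_base) for l in legacy_ids]
    )

    hidden: list[PlantedHidden] = []
    true_set = set(true_pairs)
    for a, c in true_pairs:
        hidden.append(
            PlantedHidden(
                a=a,
                c=c,
                pre_split_only=True,
                assert_after=BENCHMARK_SPLIT_DATE,
                assert_rate=assert_rate,
            )
        )
    for a in a_ids:
        for c in c_ids:
            if (a, c) not in true_set:
                hidden.append(
                    PlantedHidden(a=a, c=c, pre_split_only=True, assert_after=None)
                )
    # scale-calibration pairs: two common generic terms per pair whose
    # co-mention only emerges late in the background era, pinning the
    # co-publication list's Rmin at a stable far-below-independence value
    for i in range(n_legacy_pairs):
        hidden.append(
            PlantedHidden(
                a=legacy_ids[2 * i],
                c=legacy_ids[2 * i + 1],
                pre_split_only=True,
                assert_after=legacy_overlap_start,
                assert_rate=0.0,
            )
        )

    cfg = SyntheticConfig(
        n_docs=n_docs,
        year_range=(1988.0, 2007.33),
        concepts=tuple(concepts),
        planted_pairs=planted_pairs,
        planted_hidden=tuple(hidden),
        seed=seed,
    )
    return cfg, true_pairs


# ---------------------------------------------------------------------------
# Ambiguity fixture for the symbol-disambiguation rule


def ambiguity_fixture() -> tuple[Corpus, list[Concept], MentionIndex]:
    """Hand-built corpus exercising the gene-symbol disambiguation rule.

    One gene has full name "programmed death regulator" and symbol "PDRX1";
    a second concept is a disease.  Document F1 mentions only the symbol
    (discarded), F2 mentions the symbol plus the full-name word "death"
    (retained), F3 mentions the full name (retained, no check needed).
    """
    gene = Concept(
        "g_pdrx",
        "gene",
        (("programmed death regulator", "full_name"), ("PDRX1", "symbol")),
    )
    disease = Concept("d_grav", "disease", (("gravex syndrome", "full_name"),))
    docs = [
        DocumentRecord(
            "F1",
            "voriv lemnor",
            "tasperil PDRX1 ondrevic shalmette quorandel",
            (),
            PubDate(1995, 3, 1),
        ),
        DocumentRecord(
            "F2",
            "brevitan moskelli",
            "PDRX1 voriv death fandrossi gravex syndrome welkinore",
            (),
            PubDate(1996, 6, 1),
        ),
        DocumentRecord(
            "F3",
            "drosvane pelliturn",
            "programmed death regulator garnovex gravex syndromes hulverin",
            (),
            PubDate(1997, 9, 1),
        ),
    ]
    corpus = Corpus(tuple(docs))
    expected = MentionIndex.from_doc_concepts(
        {
            "F1": frozenset(),
            "F2": frozenset({"g_pdrx", "d_grav"}),
            "F3": frozenset({"g_pdrx", "d_grav"}),
        },
        {d.doc_id: d.pub_date for d in docs},
    )
    return corpus, [gene, disease], expected
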