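# File formats

All files are UTF-8 text; tabular files are tab-separated with a header
row.

## Medline-XML dialect

A constrained subset of the Medline citation schema, read and written by
`litdisc.corpus_io`:

```xml
<MedlineCitationSet>
  <MedlineCitation>
    <PMID>1001</PMID>
    <Article>
      <Journal><JournalIssue><PubDate>
        <Year>1998</Year><Month>04</Month><Day>02</Day>
      </PubDate></JournalIssue></Journal>
      <ArticleTitle>...</ArticleTitle>
      <Abstract><AbstractText>...</AbstractText></Abstract>
    </Article>
    <ChemicalList>
      <Chemical><NameOfSubstance>...</NameOfSubstance></Chemical>
    </ChemicalList>
  </MedlineCitation>
</MedlineCitationSet>
```

Recognized elements: `PMID`, `ArticleTitle`, `AbstractText` (several are
concatenated), `PubDate` (`Year` required; `Month` numeric or three-letter
name; `Day` optional), `NameOfSubstance` (repeated). Citations lacking a
PMID or a publication year are skipped with a logged count; duplicate PMIDs
keep the first record. No DTD validation is attempted.

## Corpus TSV

Columns `doc_id, year, title, body, substances`. `year` is `YYYY`,
`YYYY-MM` or `YYYY-MM-DD`; `substances` is `|`-separated (empty for none).
One document per line; duplicate ids keep the first.

## Thesaurus TSV

Columns `concept_id, category, keyword_type, keyword`. Rows group by
`concept_id`; `category` is one of `gene, disease, drug, pathway,
biological_process, liver_pathology`; `keyword_type` is `full_name,
symbol, alias`.

## Concordance TSV

Columns `doc_id, concept_id, category, year` — one row per non-redundant
document/concept hit. Note that documents without hits are not represented,
so an index reloaded from this export has a smaller total document count
than the source corpus.

## Score table TSV

Columns `a, b, n_a, n_b, n_ab, S, R, R_scaled, mean_year, significant,
doc_ids` — one row per scored pair; `doc_ids` is `;`-separated supporting
document ids, `significant` is 1 when `R_scaled > 40`.

## ROC TSV

Columns `cutoff, TP, FP, TN, FN, TPR, FPR`, one row per swept Ri threshold
(including ±inf sentinels), with `TPR = TP/(TP+FN)` and `FPR = FP/(FP+TN)`.

## Discovery output JSON

A list of rows, one per (relationship, intermediate):
`a, c, ri, n_intermediates, b, r_ab, r_bc, link_score, docs_ab, docs_bc`.

## Pipeline config

`configparser` syntax with sections `[inputs]`, `[simulate]`, `[score]`,
`[discover]`, `[validate]`; see the README for a worked run. `litdisc run`
writes every artifact plus `manifest.json` carrying the config hash, input
hashes, all parameters and output hashes.
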