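# suppmat

Toolkit for making article supplementary materials machine-minable:

1. **Convert** heterogeneous supplementary files (CSV/TSV, spreadsheets,
   word-processor documents, slide decks, PDFs, plain text, and compressed
   archives) into structure-preserving BioC-XML / BioC-JSON. Table grids from
   delimited, spreadsheet, and word-processor sources are preserved losslessly
   via cell-level annotations; PDF content is deliberately converted to raw
   text only (no table reconstruction).
2. **Categorize** tables: embed linearized tables with a pluggable encoder,
   cluster a labeled seed set with seeded k-means (cluster count selected by
   the Elbow method, the gap statistic, and the silhouette score), name
   clusters by their modal label with a 4-letter code registry (e.g. `GPED`
   = Gene Expression Data), and assign any table by cosine 1-nearest-neighbor
   with an `OTHR` fallback below a similarity threshold.
3. **Retrieve**: a searchable index over categorized table embeddings with
   exact brute-force cosine ranking, pre-ranked top-1000 neighbor lists, a
   type-filtered free-text query mode, a table-to-table mode, and a BioC
   fetch endpoint (≤ 50 article ids per request, > 5 MB responses flagged as
   attachments).
4. **Simulate**: a seeded synthetic-corpus generator with full ground truth
   (true media classes, grids, category labels, planted conversion failures),
   so the whole pipeline is testable offline.

## Layout

| module | role |
|---|---|
| `suppmat.bioc` | document/table model, BioC-XML + BioC-JSON codecs |
| `suppmat.extraction` | media-class detection, per-format extractors, archive expansion, conversion driver + report |
| `suppmat.embedding` | encoder protocol, deterministic hashing fixture encoder, table linearization, cosine |
| `suppmat.categorize` | k-means, WCSS/gap/silhouette, k selection, cluster naming, 1-NN assignment |
| `suppmat.index` | index build, neighbor precomputation, both search modes, BioC fetch, persistence |
| `suppmat.synth` | synthetic corpora + ground truth, labeled seed sampling, randomized BioC collections |
| `suppmat.cli` / `suppmat.service` | `suppmat` command-line interface and local HTTP service |

The default encoder is a deterministic hashing bag-of-tokens fixture
(768-dim); a production biomedical sentence encoder can be registered via
`suppmat.embedding.register_encoder` without any other change.

## CLI walkthrough

```bash
# 1. generate a seeded synthetic corpus with ground truth
suppmat simulate corpus/ --articles 24 --categories 3 --files-per-article 2 --seed 5

# 2. convert it to BioC (writes collection.xml, collection.json, report.json)
suppmat convert corpus/ bioc/

# 3. fit the category model from a labeled seed TSV (table_id<TAB>label)
suppmat cluster bioc/ labels.tsv model/ --config config.yaml

# 4. build the retrieval index + neighbor lists
suppmat index bioc/ model/model.json index.json

# 5. search either way
suppmat search index.json --query "gene expression fold change" --code GPED --top 10
suppmat search index.json --article PMC9000001 --file supp_1.csv

# 6. serve fetch + both search modes over HTTP
suppmat serve index.json --bioc-dir bioc/ --port 8080
# GET /fetch?ids=PMC9000001  |  /search/query?q=...&code=GPED  |  /search/table?article=...&file=...
```

Configuration is a single YAML file (unknown keys rejected); CLI flags
override it. Every stochastic step takes an explicit seed.

## BioC table encoding (convention)

One passage per table; passage text is the row-major grid linearization
(cells joined by TAB, rows by NEWLINE); each cell carries an annotation with
`row`/`col` infons and a character span, so the exact grid — including cells
containing tabs or newlines — is recoverable from annotations alone. Captions
are `table_caption` passages linked by a `caption_for` infon. Offsets are
0-based character offsets; annotation locations are document-scoped.
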