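{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "PSSM comparison run output",
 "type": "object",
 "required": ["meta", "results"],
 "properties": {
  "meta": {
   "type": "object",
   "required": ["version", "config", "input_digests", "timestamp"],
   "properties": {
    "version": {"type": "string"},
    "config": {"type": "object"},
    "input_digests": {"type": "object"},
    "timestamp": {"type": "string"}
   }
  },
  "results": {
   "type": "array",
   "items": {
    "type": "object",
    "required": [
     "query", "comparison", "offset", "window_length", "iws_p_win",
     "iws_sig_win", "corrected_p", "n_windows", "dissimilarity", "rank",
     "significant", "passes_dissimilarity_filter", "per_column"
    ],
    "properties": {
     "query": {"type": "string"},
     "comparison": {"type": "string"},
     "offset": {"type": "integer", "minimum": 0},
     "window_length": {"type": "integer", "minimum": 1},
     "iws_p_win": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
     "iws_sig_win": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
     "corrected_p": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
     "n_windows": {"type": "integer", "minimum": 1},
     "dissimilarity": {"type": "number", "minimum": 0},
     "rank": {"type": "integer", "minimum": 1},
     "significant": {"type": "boolean"},
     "passes_dissimilarity_filter": {"type": "boolean"},
     "per_column": {
      "type": "array",
      "items": {
       "type": "object",
       "required": [
        "similarity", "importance_query", "importance_comparison",
        "iws", "iws_p", "iwd"
       ],
       "properties": {
        "similarity": {"type": "number", "minimum": -1, "maximum": 1},
        "importance_query": {"type": "number", "minimum": 0, "maximum": 1},
        "importance_comparison": {"type": "number", "minimum": 0, "maximum": 1},
        "iws": {"type": "number", "minimum": -1, "maximum": 1},
        "iws_p": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "iwd": {"type": "number", "minimum": 0}
       }
      }
     }
    }
   }
  }
 }
}
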