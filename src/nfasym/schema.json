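{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "nfasym-experiment-dataset",
  "title": "fNIRS prefrontal-asymmetry neurofeedback experiment dataset",
  "type": "object",
  "required": ["header", "markers", "subjects"],
  "additionalProperties": false,
  "$defs": {
    "array2d": {
      "type": "object",
      "required": ["shape", "data"],
      "properties": {
        "shape": {"type": "array", "items": {"type": "integer", "minimum": 0}},
        "data": {"type": "array"}
      }
    },
    "epoch": {
      "type": "object",
      "required": ["time", "marker", "hbo", "hbo_unfiltered", "average_left", "average_right", "asymmetry"],
      "properties": {
        "time": {"type": "array", "items": {"type": "number"}, "description": "un-normalized wall-clock seconds"},
        "marker": {"type": "array", "items": {"type": "integer"}},
        "hbo": {"$ref": "#/$defs/array2d", "description": "filtered HbO, channel x time, umol/L"},
        "hbo_unfiltered": {"$ref": "#/$defs/array2d"},
        "average_left": {"type": "array", "items": {"type": "number"}},
        "average_right": {"type": "array", "items": {"type": "number"}},
        "asymmetry": {"type": "array", "items": {"type": "number"}, "description": "average_left - average_right, sample-wise"}
      }
    },
    "block": {
      "type": "object",
      "required": ["block_number", "is_practice", "success", "whole_block", "nf_epoch", "view_epoch", "mapping_feedback"],
      "properties": {
        "block_number": {"type": "integer", "minimum": 0},
        "is_practice": {"type": "boolean"},
        "success": {"type": "boolean"},
        "whole_block": {"$ref": "#/$defs/epoch"},
        "view_epoch": {"oneOf": [{"$ref": "#/$defs/epoch"}, {"type": "null"}]},
        "nf_epoch": {"$ref": "#/$defs/epoch"},
        "mapping_min": {"type": "number", "description": "View mean + 1.28 x View SD; absent for fixed-mapping protocols"},
        "mapping_max": {"type": "number", "description": "mapping_min + View variation range; absent for fixed-mapping protocols"},
        "mapping_feedback": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}}
      }
    }
  },
  "properties": {
    "header": {
      "type": "object",
      "required": ["sampling_rate", "number_of_channels", "filter_kernel", "experiment_id"],
      "properties": {
        "sampling_rate": {"type": "number", "exclusiveMinimum": 0},
        "number_of_channels": {"type": "integer", "minimum": 1},
        "filter_kernel": {"type": "array", "items": {"type": "number"}, "minItems": 1},
        "experiment_id": {"enum": ["ANG", "RAP", "HEU"]}
      }
    },
    "markers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["num", "description"],
        "properties": {
          "num": {"type": "integer"},
          "description": {"type": "string"}
        }
      }
    },
    "subjects": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "channel_data", "asymmetry_data", "time", "marker", "blocks"],
        "properties": {
          "id": {"type": "string", "pattern": "^[0-9]{4}$", "description": "MDDN convention: month, day, order on day"},
          "channel_data": {"$ref": "#/$defs/array2d", "description": "(channel, time, block) tensor"},
          "asymmetry_data": {"$ref": "#/$defs/array2d", "description": "(time, block) matrix"},
          "time": {"type": "array", "items": {"type": "number"}, "description": "normalized block-relative seconds"},
          "marker": {"type": "array", "items": {"type": "integer"}},
          "blocks": {"type": "array", "items": {"$ref": "#/$defs/block"}}
        }
      }
    }
  }
}
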