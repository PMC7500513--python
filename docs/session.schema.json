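{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "percross session",
  "description": "Nested session document mirroring events.csv/trajectories.csv plus the world configuration.",
  "type": "object",
  "required": ["world", "teams"],
  "properties": {
    "world": {
      "type": "object",
      "properties": {
        "space_length": {"type": "number", "exclusiveMinimum": 0},
        "object_length": {"type": "number", "exclusiveMinimum": 0},
        "shadow_offset": {"type": "number"},
        "trial_duration": {"type": "number", "exclusiveMinimum": 0},
        "tick": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "teams": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["team_id", "trials"],
        "properties": {
          "team_id": {"type": "integer"},
          "trials": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["trial_number"],
              "properties": {
                "trial_number": {"type": "integer", "minimum": 1},
                "clicks": {
                  "type": "array",
                  "maxItems": 2,
                  "items": {
                    "type": "object",
                    "required": ["player", "time_s", "position"],
                    "properties": {
                      "player": {"enum": [1, 2]},
                      "time_s": {"type": "number", "minimum": 0},
                      "position": {"type": "number", "minimum": 0},
                      "target": {
                        "enum": ["other_avatar", "shadow", "static", "unknown", null]
                      }
                    }
                  }
                },
                "pas": {
                  "type": "array",
                  "maxItems": 2,
                  "items": {
                    "type": "object",
                    "required": ["player", "value"],
                    "properties": {
                      "player": {"enum": [1, 2]},
                      "value": {"enum": [1, 2, 3, 4]}
                    }
                  }
                },
                "static_positions": {
                  "type": "array", "minItems": 2, "maxItems": 2,
                  "items": {"type": "number"}
                },
                "times_s": {"type": "array", "items": {"type": "number"}},
                "avatar_positions": {
                  "type": "array",
                  "items": {
                    "type": "array", "minItems": 2, "maxItems": 2,
                    "items": {"type": "number"}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
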