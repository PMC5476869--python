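{
  "$defs": {
    "ComparisonReport": {
      "additionalProperties": false,
      "properties": {
        "area_earlier": {
          "title": "Area Earlier",
          "type": "number"
        },
        "area_later": {
          "title": "Area Later",
          "type": "number"
        },
        "earlier_segment": {
          "title": "Earlier Segment",
          "type": "string"
        },
        "earlier_session": {
          "title": "Earlier Session",
          "type": "integer"
        },
        "f_cut": {
          "title": "F Cut",
          "type": "number"
        },
        "later_segment": {
          "title": "Later Segment",
          "type": "string"
        },
        "later_session": {
          "title": "Later Session",
          "type": "integer"
        },
        "name": {
          "title": "Name",
          "type": "string"
        },
        "percent_area_change": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Percent Area Change"
        },
        "power_earlier": {
          "title": "Power Earlier",
          "type": "number"
        },
        "power_later": {
          "title": "Power Later",
          "type": "number"
        },
        "ratio": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ratio"
        },
        "verdict": {
          "title": "Verdict",
          "type": "string"
        }
      },
      "required": [
        "name",
        "earlier_session",
        "later_session",
        "earlier_segment",
        "later_segment",
        "f_cut",
        "power_earlier",
        "power_later",
        "ratio",
        "verdict",
        "area_earlier",
        "area_later",
        "percent_area_change"
      ],
      "title": "ComparisonReport",
      "type": "object"
    },
    "ParticipantReport": {
      "additionalProperties": false,
      "properties": {
        "comparisons": {
          "items": {
            "$ref": "#/$defs/ComparisonReport"
          },
          "title": "Comparisons",
          "type": "array"
        },
        "group": {
          "title": "Group",
          "type": "string"
        },
        "participant": {
          "title": "Participant",
          "type": "string"
        },
        "segments": {
          "items": {
            "$ref": "#/$defs/SegmentReport"
          },
          "title": "Segments",
          "type": "array"
        }
      },
      "required": [
        "participant",
        "group",
        "segments",
        "comparisons"
      ],
      "title": "ParticipantReport",
      "type": "object"
    },
    "Provenance": {
      "additionalProperties": false,
      "properties": {
        "config_sha256": {
          "title": "Config Sha256",
          "type": "string"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "title": "Seed"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "config_sha256",
        "version",
        "seed"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "SegmentReport": {
      "additionalProperties": false,
      "properties": {
        "curve_area": {
          "title": "Curve Area",
          "type": "number"
        },
        "discontinuities": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Discontinuities",
          "type": "object"
        },
        "duration": {
          "title": "Duration",
          "type": "number"
        },
        "n_samples": {
          "title": "N Samples",
          "type": "integer"
        },
        "range_pitch": {
          "title": "Range Pitch",
          "type": "number"
        },
        "range_roll": {
          "title": "Range Roll",
          "type": "number"
        },
        "range_yaw": {
          "title": "Range Yaw",
          "type": "number"
        },
        "segment": {
          "title": "Segment",
          "type": "string"
        },
        "session": {
          "title": "Session",
          "type": "integer"
        }
      },
      "required": [
        "session",
        "segment",
        "n_samples",
        "duration",
        "range_yaw",
        "range_pitch",
        "range_roll",
        "curve_area",
        "discontinuities"
      ],
      "title": "SegmentReport",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "complete": {
      "title": "Complete",
      "type": "boolean"
    },
    "participants": {
      "items": {
        "$ref": "#/$defs/ParticipantReport"
      },
      "title": "Participants",
      "type": "array"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "provenance",
    "participants",
    "warnings",
    "complete"
  ],
  "title": "StudyReport",
  "type": "object"
}
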