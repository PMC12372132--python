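{
  "title": "EASE run-report summary",
  "type": "object",
  "required": [
    "n",
    "categories",
    "logrank",
    "calibration",
    "provenance"
  ],
  "properties": {
    "n": {
      "type": "integer"
    },
    "categories": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": [
          "n",
          "proportion",
          "incidence_12mo",
          "crude_recurrence"
        ],
        "properties": {
          "n": {
            "type": "integer"
          },
          "proportion": {
            "type": "number"
          },
          "incidence_12mo": {
            "type": [
              "number",
              "null"
            ]
          },
          "crude_recurrence": {
            "type": [
              "number",
              "null"
            ]
          }
        }
      }
    },
    "logrank": {
      "type": [
        "object",
        "null"
      ]
    },
    "calibration": {
      "type": [
        "object",
        "null"
      ]
    },
    "provenance": {
      "type": "object"
    }
  }
}
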