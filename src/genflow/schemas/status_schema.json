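{
  "$defs": {
    "StatusJob": {
      "description": "One job record in the status report.",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "step": {
          "title": "Step",
          "type": "string"
        },
        "command_digest": {
          "pattern": "^[0-9a-f]{32}$",
          "title": "Command Digest",
          "type": "string"
        },
        "inputs": {
          "items": {
            "type": "string"
          },
          "title": "Inputs",
          "type": "array"
        },
        "outputs": {
          "items": {
            "type": "string"
          },
          "title": "Outputs",
          "type": "array"
        },
        "dependencies": {
          "items": {
            "type": "string"
          },
          "title": "Dependencies",
          "type": "array"
        },
        "planned_status": {
          "pattern": "^(submit|skipped)$",
          "title": "Planned Status",
          "type": "string"
        }
      },
      "required": [
        "name",
        "step",
        "command_digest",
        "inputs",
        "outputs",
        "dependencies",
        "planned_status"
      ],
      "title": "StatusJob",
      "type": "object"
    }
  },
  "description": "Status JSON written for every run; the portal-facing contract.",
  "properties": {
    "pipeline": {
      "title": "Pipeline",
      "type": "string"
    },
    "protocol": {
      "title": "Protocol",
      "type": "string"
    },
    "generated_at": {
      "title": "Generated At",
      "type": "string"
    },
    "jobs": {
      "items": {
        "$ref": "#/$defs/StatusJob"
      },
      "title": "Jobs",
      "type": "array"
    }
  },
  "required": [
    "pipeline",
    "protocol",
    "generated_at",
    "jobs"
  ],
  "title": "StatusReport",
  "type": "object"
}
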